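"""THI computation and thermal-comfort labelling of recording windows.

Simulates one logged day whose hours move from cold through comfort to
heat, aggregates the 5-min records to hourly means, and labels two
15-min recording windows by the THI of the hours they overlap.
"""

import pandas as pd

from hensight import hourly_means, label_recordings, simulate_thermal, thi

print(f"THI(25 C, 50% RH) = {thi(25, 50):.2f}  (comfort: 59 < THI < 78)")
print(f"THI(30 C, 70% RH) = {thi(30, 70):.2f}  (> 78 -> heat stress)")
print()

schedule = ["cold"] * 6 + ["comfort"] * 10 + ["heat"] * 8
log = simulate_thermal(24, schedule, seed=3, start="2021-06-01")
hourly = hourly_means(log)
print(hourly.iloc[[0, 8, 20]].to_string(index=False))
print()

windows = pd.DataFrame(
    {
        "recording_id": ["morning", "afternoon"],
        "start": pd.to_datetime(["2021-06-01 08:00", "2021-06-01 15:00"]),
        "end": pd.to_datetime(["2021-06-01 08:15", "2021-06-01 15:15"]),
    }
)
print(label_recordings(windows, hourly).to_string(index=False))
print()
print("Each window inherits the class of the mean THI over the hours it spans.")
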