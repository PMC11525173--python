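"""Spacing-effect and extinction-timing simulations.

Six training bouts at ISIs from 60 to 900 s, reading the gamma1 and
alpha3 biases at 5 min, 3 h and 24 h; then three-bout extinction starting
10-120 min after attractive-pair conditioning, reading the 3-h and 35-min
alpha3 biases against the no-extinction control.

Writes results/isi_sweep.csv and results/extinction_timing.csv.
"""

import pathlib

import pandas as pd

from mushbody.circuit import ground_truth_params
from mushbody.protocols import extinction_experiment, isi_sweep

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    params = ground_truth_params()

    isis = [60.0, 120.0, 240.0, 360.0, 600.0, 900.0]
    sweep = isi_sweep(params, isis, readout_sessions=("5min", "3h", "24h"))
    rows = [(isi, n, s, b) for isi in isis
            for n in ("Mg1", "Ma3")
            for s, b in sweep[isi][n].items() if s != "pre"]
    df = pd.DataFrame(rows, columns=["isi_s", "neuron", "session", "bias_hz"])
    df.to_csv(OUT / "isi_sweep.csv", index=False)
    m24 = df[(df.neuron == "Ma3") & (df.session == "24h")]
    best = m24.loc[m24["bias_hz"].idxmin(), "isi_s"]
    print("24-h alpha3 bias by ISI (Hz):")
    print(m24[["isi_s", "bias_hz"]].round(3).to_string(index=False))
    print(f"-> deepest 24-h depression at ISI {best:.0f} s (spacing effect)")

    ctrl3h = extinction_experiment(params, "attractive", None)["readout"]
    rows = [("none", 180.0, ctrl3h, 1.0)]
    for start in (10, 30, 60, 120):
        b = extinction_experiment(params, "attractive",
                                  start * 60.0)["readout"]
        rows.append((str(start), 180.0, b, abs(b) / abs(ctrl3h)))
    c35 = extinction_experiment(params, "attractive", None,
                                readout=35 * 60.0)["readout"]
    e35 = extinction_experiment(params, "attractive", 600.0,
                                readout=35 * 60.0)["readout"]
    rows += [("none", 35.0, c35, 1.0), ("10", 35.0, e35, abs(e35) / abs(c35))]
    ext = pd.DataFrame(rows, columns=["extinction_start_min", "readout_min",
                                      "bias_hz", "vs_control"])
    ext.to_csv(OUT / "extinction_timing.csv", index=False)
    print("\nExtinction timing (attractive pair):")
    print(ext.round(3).to_string(index=False))
    print("-> 3-h memory erased by extinction from 60 min on; 10-min "
          "extinction instead deepens the 35-min trace (self-reinforcing "
          "CS+).")


if __name__ == "__main__":
    main()
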