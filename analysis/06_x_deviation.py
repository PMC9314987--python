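"""X-vs-autosome deviation statistics.

Two parts: (1) a count-level simulation study on a pig-like karyotype with
a planted 50% X deficiency on the Ne-adjusted scale, showing the estimator
recovers the planted deficit and the studentised outlier test rejects; and
(2) the same machinery applied to an excess scenario, mirroring the
duplication/inversion side of the X story.
"""

import numpy as np
import pandas as pd
from analysis_config import RESULTS

from asmcompare.chromstats import (deviation_table, simulate_count_table)

N_SEEDS = 200


def summarise(x_deficiency: float, label: str, rng) -> dict:
    devs, ps = [], []
    for _ in range(N_SEEDS):
        table = simulate_count_table(rng, x_deficiency=x_deficiency)
        row = deviation_table(table, ["DEL"]).iloc[0]
        devs.append(row["deviation_pct"])
        ps.append(row["p_value"])
    frac_sig = float(np.mean(np.array(ps) < 0.001))
    print(f"{label}: mean deviation {np.mean(devs):+.1f}% "
          f"(planted {100 * -x_deficiency:+.0f}%), "
          f"p < 0.001 in {100 * frac_sig:.0f}% of {N_SEEDS} seeds")
    return {"scenario": label, "planted_pct": -100 * x_deficiency,
            "mean_deviation_pct": float(np.mean(devs)),
            "sd_deviation_pct": float(np.std(devs, ddof=1)),
            "frac_p_below_0.001": frac_sig}


def main() -> None:
    rng = np.random.default_rng(606)
    rows = [
        summarise(0.5, "deficiency_50pct", rng),
        summarise(0.0, "null", rng),
        summarise(-1.0, "excess_100pct", rng),
    ]
    print("note: the outlier test measures distance from the raw autosome "
          "line, so under the null (no deficit beyond Ne scaling) it still "
          "rejects whenever the 3/4 Ne effect itself is detectable; the "
          "deviation estimate, which is Ne-adjusted, correctly centres on 0.")
    frame = pd.DataFrame(rows)
    frame.to_csv(RESULTS / "x_deviation_recovery.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS / 'x_deviation_recovery.tsv'}")


if __name__ == "__main__":
    main()
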