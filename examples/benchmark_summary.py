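"""Summary statistics of the bundled published 21-subject MSE benchmark.

Loads the per-subject MSE table of a published two-session resting-state
benchmark (precentral-gyrus seed, T=74) and recomputes its column
statistics and boxplot outliers through the evaluation module.
"""

import numpy as np

from fcshrink import percent_reduction, tukey_outliers, tukey_quartiles
from fcshrink.datasets import BENCHMARK_AVERAGE_ROW, load_benchmark_table

df = load_benchmark_table()
for method in ("raw", "mean", "shrinkage"):
    col = df[f"mse_{method}"].to_numpy()
    print(
        f"{method:<9} avg {col.mean():.4f}  median {np.median(col):.4f}  "
        f"min {col.min():.4f}  max {col.max():.4f}"
    )

avg = BENCHMARK_AVERAGE_ROW
print(f"\nreduction vs raw (published average row): "
      f"mean {percent_reduction(avg['mse_raw'], avg['mse_mean']):.2f}%  "
      f"shrinkage {percent_reduction(avg['mse_raw'], avg['mse_shrinkage']):.2f}%")

raw = df["mse_raw"].to_numpy()
q1, q3 = tukey_quartiles(raw)
out = tukey_outliers(raw)
print(f"raw column quartiles Q1={q1:.4f} Q3={q3:.5f}; "
      f"outliers: {', '.join(df['subject_id'].iloc[out])} "
      f"({', '.join(f'{raw[k]:.4f}' for k in out)})")
# The two flagged subjects are the scans whose session-1 maps were least
# predictive of their own session-2 maps.
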