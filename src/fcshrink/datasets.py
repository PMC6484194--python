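"""Bundled reference data.

The package ships the per-subject MSE table of a published 21-subject
two-session resting-state benchmark (precentral-gyrus seed, 74 time points
per scan, predictors scored on the Fisher-Z scale).  The underlying scans
are not redistributable, but the printed per-subject MSEs are enough to
recompute every summary statistic of that analysis — column averages,
medians, extremes, percent reductions and boxplot outliers — through this
package's evaluation code.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_benchmark_table", "BENCHMARK_AVERAGE_ROW"]

#: the benchmark's own printed average row (average MSE per method); the
#: per-subject table reproduces these to its 4-decimal printing precision
BENCHMARK_AVERAGE_ROW = {"mse_raw": 0.2169, "mse_mean": 0.1118, "mse_shrinkage": 0.1103}


def load_benchmark_table() -> pd.DataFrame:
    """Per-subject MSE benchmark: one row per subject, columns subject_id,
    mse_raw, mse_mean, red_mean_pct, mse_shrinkage, red_shrink_pct."""
    ref = resources.files("fcshrink.data").joinpath("benchmark_mse.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return df
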