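"""Published summary tables for the 14-population Arabidopsis NAM panel.

The panel consists of 14 Versailles recombinant inbred line (RIL)
populations that share Col-0 as recurrent parent, each crossed to a
different alternate accession, genotyped by GBS and re-mapped.  Two small
summary tables ship with the package:

* per-population metadata and map metrics (population size, marker counts,
  map length and interval sizes, missing-data rates before and after
  conservative imputation), used both as the default study conditions for
  the synthetic-data generator and as fixtures for the aggregation code;
* per-population results of the small-effect QTL marker-density simulation
  (estimated PVE and 1.5-LOD interval sizes under the dense GBS map versus
  the original sparse map).
"""

from __future__ import annotations

from io import StringIO

import numpy as np
import pandas as pd

_RIL_SUMMARY_TSV = """\
population\talt_parent\tpopulation_size\ttotal_markers\tgbs_markers\toverall_length_cM\tavg_interval_cM\tmax_interval_cM\tmissing_gbs_pct\tmissing_post_imputation_pct
2RV\tbla1\t141\t641\t563\t443.1\t0.7\t13.9\t27.1\t3.2
3RV\ttsu0\t145\t1254\t1175\t449.8\t0.4\t6.4\t23.6\t1.4
4RV\tnok1\t144\t1243\t1158\t462.6\t0.4\t7.1\t23.0\t1.1
6RV\tri0\t144\t1503\t1419\t489.5\t0.3\t7.5\t16.6\t0.8
8RV\tcvi0\t147\t1615\t1525\t634.5\t0.4\t11.7\t22.7\t1.0
13RV\tsha\t148\t796\t711\t417.4\t0.5\t7.9\t20.2\t1.3
17RV\tge0\t149\t1201\t1119\t485.0\t0.4\t5.0\t23.6\t1.2
19RV\tcan0\t148\t1561\t1477\t481.5\t0.3\t6.1\t26.0\t1.2
20RV\tbur0\t142\t1344\t1257\t433.0\t0.3\t5.5\t21.5\t1.1
21RV\tblh1\t137\t1074\t1000\t485.1\t0.5\t6.8\t23.3\t1.3
23RV\tyo0\t150\t1351\t1269\t477.5\t0.4\t7.2\t20.6\t0.8
27RV\toy0\t149\t1349\t1264\t488.7\t0.4\t9.7\t19.7\t1.1
28RV\tjea\t147\t1435\t1348\t482.2\t0.3\t6.5\t17.8\t0.8
29RV\tita0\t137\t1183\t1096\t430.8\t0.4\t9.0\t16.4\t0.9
"""

# Small-effect QTL density comparison, per population: mean estimated PVE (%)
# and mean 1.5-LOD interval (cM) under dense (GBS+original) vs sparse
# (original-only) marker sets, percent interval reduction, and percent of
# QTL detected with the sparse set alone.
_QTL_DENSITY_TSV = """\
population\talt_parent\tpve_dense_pct\tpve_sparse_pct\tinterval_dense_cM\tinterval_sparse_cM\tinterval_reduction_pct\tdetected_sparse_pct
2RV\tbla1\t10.0\t9.7\t25.2\t29.1\t13.4\t74.2
3RV\ttsu0\t10.1\t9.6\t23.3\t28.1\t17.1\t75.7
4RV\tnok1\t10.5\t9.9\t21.3\t28.5\t25.3\t75.9
6RV\tri0\t10.3\t9.5\t24.5\t34.1\t28.2\t79.1
8RV\tcvi0\t10.6\t9.8\t24.2\t36.9\t34.4\t78.0
13RV\tsha\t9.8\t9.3\t21.0\t27.1\t22.5\t80.3
17RV\tge0\t9.9\t9.2\t21.9\t28.4\t22.9\t78.2
19RV\tcan0\t10.1\t9.5\t22.6\t30.6\t26.1\t75.7
20RV\tbur0\t10.1\t9.5\t23.8\t32.8\t27.4\t75.5
21RV\tblh1\t10.7\t10.0\t24.7\t31.6\t21.8\t68.7
23RV\tyo0\t10.2\t9.4\t21.1\t29.9\t29.4\t74.4
27RV\toy0\t10.0\t9.4\t24.5\t29.2\t16.1\t74.9
28RV\tjea\t10.1\t9.4\t22.3\t28.6\t22.0\t78.6
29RV\tita0\t10.7\t10.0\t22.0\t27.5\t20.0\t76.9
"""


def ril_population_summary() -> pd.DataFrame:
    """Per-population metadata and map metrics for the 14 RIL populations."""
    return pd.read_csv(StringIO(_RIL_SUMMARY_TSV), sep="\t")


def qtl_density_summary() -> pd.DataFrame:
    """Per-population small-effect QTL marker-density simulation summary."""
    return pd.read_csv(StringIO(_QTL_DENSITY_TSV), sep="\t")


def aggregate_ril_summary(table: pd.DataFrame | None = None) -> dict:
    """Panel-level aggregates of the per-population summary.

    Returns total line count, mean GBS marker count, mean average and maximum
    map interval, and mean missing-data rates before and after imputation.
    """
    t = ril_population_summary() if table is None else table
    return {
        "population_size_sum": int(t["population_size"].sum()),
        "gbs_markers_mean": float(t["gbs_markers"].mean()),
        "avg_interval_mean_cM": float(t["avg_interval_cM"].mean()),
        "max_interval_mean_cM": float(t["max_interval_cM"].mean()),
        "missing_gbs_mean_pct": float(t["missing_gbs_pct"].mean()),
        "missing_post_imputation_mean_pct": float(
            t["missing_post_imputation_pct"].mean()
        ),
    }


def aggregate_qtl_density(table: pd.DataFrame | None = None) -> dict:
    """Panel-level aggregates of the small-effect density comparison."""
    t = qtl_density_summary() if table is None else table
    return {
        "interval_reduction_mean_pct": float(t["interval_reduction_pct"].mean()),
        "pve_dense_mean_pct": float(t["pve_dense_pct"].mean()),
        "pve_sparse_mean_pct": float(t["pve_sparse_pct"].mean()),
        "detected_sparse_mean_pct": float(t["detected_sparse_pct"].mean()),
    }


def allele_replication(n_lines: int, n_founders: int) -> float:
    """Expected number of lines carrying a minor allele at its minimum
    frequency in a balanced multiparent panel.

    In a biparental RIL population the minimum minor-allele frequency is 1/2,
    so any subset of a NAM panel containing the segregating population keeps
    at least ``n_lines / 2`` carriers.  In an n-founder intercross (e.g., a
    19-founder MAGIC panel) the minimum frequency is ``1 / n_founders``.
    """
    if n_lines <= 0 or n_founders <= 0:
        raise ValueError("counts must be positive")
    return n_lines / n_founders
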