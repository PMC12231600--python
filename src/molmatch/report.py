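"""Assemble the full comparison report.

The report is a single JSON-serializable dictionary whose sections mirror
the analysis stages: tag sharing with per-length-bin fractions, the
annotation crosswalk, cell-set counts, QC distributions, per-category
isoform/read accounting under both filter modes, differential-expression
summaries and paired-cell embedding distances.  Totals are cross-checked so
the report is internally consistent, and serialization is deterministic.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd


def _clean(obj):
    """Recursively convert numpy/pandas scalars for stable JSON output."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, pd.DataFrame):
        return _clean(obj.to_dict(orient="index"))
    if isinstance(obj, pd.Series):
        return _clean(obj.to_dict())
    return obj


def build_report(sections: dict) -> dict:
    """Build the comparison report from whatever stages completed.

    Missing stages appear as explicit ``null`` entries so a partial run
    still yields a valid report skeleton.
    """
    skeleton = ["config", "generation", "preprocessing", "tag_sharing",
                "crosswalk", "cell_calling", "qc", "counting",
                "differential_expression", "length_bias", "embedding"]
    report = {name: _clean(sections[name]) if name in sections else None
              for name in skeleton}

    sharing = report.get("tag_sharing") or {}
    if {"n_shared", "n_short_only", "n_long_only", "n_union"} <= sharing.keys():
        total = (sharing["n_shared"] + sharing["n_short_only"]
                 + sharing["n_long_only"])
        assert total == sharing["n_union"], "tag sharing totals inconsistent"
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
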