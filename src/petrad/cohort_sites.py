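"""Anatomic-site involvement frequencies.

Utilities to tabulate where patients' largest nodal and extranodal lesions
sit, both for segmented synthetic cohorts and for the published reference
DLBCL CAR-T cohort whose per-site patient counts ship with the package
(``petrad/data/site_counts.json``; e.g. nodal disease most often involves
the abdomen, 58 of 124 patients).
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

__all__ = ["load_reference_site_counts", "site_frequencies", "reference_site_frequencies"]


def load_reference_site_counts() -> dict:
    with resources.files("petrad.data").joinpath("site_counts.json").open() as fh:
        return json.load(fh)


def site_frequencies(counts: dict[str, int], n_patients: int) -> pd.DataFrame:
    """Percentage of patients involved per site, descending."""
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    rows = [
        {"site": site, "n": n, "pct": 100.0 * n / n_patients}
        for site, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["site", "n", "pct"])


def reference_site_frequencies(compartment: str) -> pd.DataFrame:
    """Site percentages of the reference cohort ('nodal' or 'extranodal')."""
    data = load_reference_site_counts()
    if compartment not in ("nodal", "extranodal"):
        raise ValueError("compartment must be 'nodal' or 'extranodal'")
    block = data[compartment]
    return site_frequencies(block["sites"], block["n_patients"])
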