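"""Packaged group-level reference tables.

Three TSV fixtures carry the published group means, SDs, fold changes
and p-value displays of the ceruloplasmin-knockout (CpKO) vs wild-type
(WT) mouse study the pipeline reproduces:

* ``table_adipose_lipids.tsv`` -- lipid classes in perigonadal adipose
  tissue at 10 months (mM per mg fresh weight);
* ``table_liver_lipids.tsv`` -- lipid classes in liver at 10 months
  (mM per mg dry weight);
* ``table_liver_mrs.tsv`` -- in vivo MRS measurands (IHLC, TG index and
  FA composition indices) at 6 and 10 months.

These are group-level summaries (n = 5 per group), not per-animal data;
the cohort generator uses them as the default study conditions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .synthetic import CohortGroup, CohortSpec

__all__ = [
    "load_adipose_lipid_table",
    "load_liver_lipid_table",
    "load_liver_mrs_table",
    "liver_lipid_cohort_spec",
    "mrs_cohort_spec",
]

_GROUP_N = 5


def _load(name: str) -> pd.DataFrame:
    with resources.files("lipospec.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_adipose_lipid_table() -> pd.DataFrame:
    """Adipose-tissue lipid classes at 10 months (mM per mg FW)."""
    return _load("table_adipose_lipids.tsv")


def load_liver_lipid_table() -> pd.DataFrame:
    """Liver lipid classes at 10 months (mM per mg DW)."""
    return _load("table_liver_lipids.tsv")


def load_liver_mrs_table() -> pd.DataFrame:
    """In vivo liver MRS measurands at 6 and 10 months."""
    return _load("table_liver_mrs.tsv")


def liver_lipid_cohort_spec(seed: int = 0, n: int = _GROUP_N) -> CohortSpec:
    """Two-group (CpKO vs WT, 10 months) cohort spec with the liver
    lipid-class means and SDs as study conditions."""
    t = load_liver_lipid_table().set_index("lipid_class")
    return CohortSpec(
        groups=(
            CohortGroup(
                "CpKO", 10, n,
                means=t["cpko_mean"].to_dict(), sds=t["cpko_sd"].to_dict(),
            ),
            CohortGroup(
                "WT", 10, n,
                means=t["wt_mean"].to_dict(), sds=t["wt_sd"].to_dict(),
            ),
        ),
        seed=seed,
    )


def mrs_cohort_spec(seed: int = 0, n: int = _GROUP_N) -> CohortSpec:
    """Four-group (genotype x age) cohort spec with the MRS measurand
    means and SDs as study conditions."""
    t = load_liver_mrs_table().set_index("measurand")
    groups = []
    for genotype, age, prefix in (
        ("CpKO", 6, "cpko6"),
        ("WT", 6, "wt6"),
        ("CpKO", 10, "cpko10"),
        ("WT", 10, "wt10"),
    ):
        groups.append(
            CohortGroup(
                genotype, age, n,
                means=t[f"{prefix}_mean"].to_dict(),
                sds=t[f"{prefix}_sd"].to_dict(),
            )
        )
    return CohortSpec(groups=tuple(groups), seed=seed)
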