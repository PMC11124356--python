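"""Delimited-text readers and writers.

All files are comma-separated UTF-8 with a header row and "." decimals;
data files carry fractions, never percentages. Stable schemas:

* designs:   ``mix_id, strain, weight_g, potency_tfu_per_g``
* profiles:  ``sample_id, taxon, fraction`` (long form)
* report:    ``mix_id, taxon, predicted, observed, absolute_difference``
* KIDMED items:      ``item_id, description, polarity``
* KIDMED responses:  ``participant_id, q1..q16`` (yes/no, y/n, 1/0,
  true/false; case-insensitive)
* cohort tables: as produced by :mod:`bifidopanel.cohort`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from bifidopanel.cohort import Cohort
from bifidopanel.kidmed import KidmedItem, KidmedResponses
from bifidopanel.mockmix import (
    AbundanceProfile,
    MixComponent,
    MixDesign,
    StrainCulture,
    ValidationReport,
)

__all__ = [
    "write_designs", "read_designs", "write_profiles", "read_profiles",
    "write_validation_report", "read_kidmed_items", "read_kidmed_responses",
    "write_cohort", "read_cohort", "parse_yes_no",
]

_TRUE = {"yes", "y", "1", "true", "t"}
_FALSE = {"no", "n", "0", "false", "f"}


def parse_yes_no(value) -> bool:
    """Parse a yes/no cell; accepts yes/no, y/n, 1/0, true/false."""
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise ValueError(f"cannot interpret {value!r} as yes/no")


def write_designs(
    designs: list[MixDesign], potencies: dict[str, float], path: str | Path
) -> None:
    rows = [
        (d.mix_id, c.strain.species_label, c.weight, potencies[c.strain.species_label])
        for d in designs
        for c in d.components
    ]
    pd.DataFrame(
        rows, columns=["mix_id", "strain", "weight_g", "potency_tfu_per_g"]
    ).to_csv(path, index=False)


def read_designs(path: str | Path) -> tuple[list[MixDesign], dict[str, float]]:
    """Read a designs table back into designs plus the potency map."""
    df = pd.read_csv(path)
    required = {"mix_id", "strain", "weight_g", "potency_tfu_per_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    potencies: dict[str, float] = {}
    strains: dict[str, StrainCulture] = {}
    for _, r in df.iterrows():
        label = str(r["strain"])
        pot = float(r["potency_tfu_per_g"])
        if label in potencies and potencies[label] != pot:
            raise ValueError(f"{path}: inconsistent potency for strain {label!r}")
        potencies[label] = pot
        strains.setdefault(label, StrainCulture(label, label, pot))
    designs = []
    for mix_id, sub in df.groupby("mix_id", sort=False):
        comps = tuple(
            MixComponent(strains[str(r["strain"])], float(r["weight_g"]))
            for _, r in sub.iterrows()
        )
        designs.append(
            MixDesign(str(mix_id), comps, total_weight=sum(c.weight for c in comps))
        )
    return designs, potencies


def write_profiles(profiles: list[AbundanceProfile], path: str | Path) -> None:
    rows = [
        (p.sample_id, taxon, frac)
        for p in profiles
        for taxon, frac in p.abundances.items()
    ]
    pd.DataFrame(rows, columns=["sample_id", "taxon", "fraction"]).to_csv(
        path, index=False
    )


def read_profiles(path: str | Path) -> list[AbundanceProfile]:
    df = pd.read_csv(path)
    missing = {"sample_id", "taxon", "fraction"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        AbundanceProfile(
            str(sid), {str(r["taxon"]): float(r["fraction"]) for _, r in sub.iterrows()}
        )
        for sid, sub in df.groupby("sample_id", sort=False)
    ]


def write_validation_report(report: ValidationReport, path: str | Path) -> None:
    report.pairs.to_csv(path, index=False)


def read_kidmed_items(path: str | Path) -> list[KidmedItem]:
    df = pd.read_csv(path)
    missing = {"item_id", "description", "polarity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        KidmedItem(int(r["item_id"]), str(r["description"]), int(r["polarity"]))
        for _, r in df.iterrows()
    ]


def read_kidmed_responses(path: str | Path) -> list[KidmedResponses]:
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise ValueError(f"{path}: missing column 'participant_id'")
    qcols = [c for c in df.columns if c.startswith("q")]
    out = []
    for _, r in df.iterrows():
        answers = {
            int(c[1:]): parse_yes_no(r[c]) for c in qcols if not pd.isna(r[c])
        }
        out.append(KidmedResponses(str(r["participant_id"]), answers))
    return out


_COHORT_FILES = {
    "participants": "participants.csv",
    "microbiome": "microbiome.csv",
    "metabolites": "metabolites.csv",
    "kidmed": "kidmed.csv",
}


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for attr, fname in _COHORT_FILES.items():
        path = outdir / fname
        getattr(cohort, attr).to_csv(path, index=False)
        paths[attr] = path
    return paths


def read_cohort(indir: str | Path) -> Cohort:
    indir = Path(indir)
    tables = {}
    for attr, fname in _COHORT_FILES.items():
        path = indir / fname
        if not path.exists():
            raise FileNotFoundError(f"cohort table missing: {path}")
        tables[attr] = pd.read_csv(path)
    return Cohort(**tables)
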