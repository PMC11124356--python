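"""Synthetic three-group study cohort: controls, type 1 diabetes, obese.

The generator emulates the structure of a paediatric cohort (ages 7-17)
with three groups — 40 healthy controls, 40 children with type 1
diabetes (T1D) and 18 children with obesity — and four linked tables per
cohort:

* participants: id, group, sex, age, BMI (and HbA1c for the T1D group);
* microbiome: relative abundances of eight *Bifidobacterium*
  (sub)species, compositional rows summing to one;
* metabolites: twelve urinary analytes (nine short-chain fatty acids and
  three branched-chain amino acids) in mmol per gram creatinine;
* KIDMED: sixteen yes/no diet items plus the derived score.

Group differences are injected through an :class:`EffectTemplate` of
multiplicative effects. Effect *directions* follow the study findings
(e.g. *B. longum* subs. *infantis* and *B. breve* enriched and
*B. bifidum* depleted in obesity; most short-chain fatty acids elevated
in T1D; a higher diet score in the obese group); effect *magnitudes* are
synthetic choices, since only boxplot figures — not numbers — document
the real ones.

The microbiome layer is zero-inflated compositional: per taxon a
Bernoulli presence draw (so a taxon can become rarer, not just less
abundant, in a group), then a Dirichlet-style gamma draw whose base
weights are scaled by the group's multipliers, renormalised per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bifidopanel import kidmed as _kidmed

__all__ = [
    "GroupSpec", "EffectTemplate", "Cohort", "TAXA", "METABOLITES",
    "GROUPS", "default_study_design", "default_effect_template",
    "null_effect_template", "generate_participants", "generate_microbiome",
    "generate_metabolites", "generate_kidmed", "generate_cohort",
    "normalize_to_creatinine",
]

GROUPS = ("control", "t1d", "obese")

#: controlled vocabulary for the eight measured (sub)species
TAXA = (
    "longum subs. longum",
    "longum subs. infantis",
    "animalis subs. animalis",
    "animalis subs. lactis",
    "bifidum",
    "breve",
    "adolescentis",
    "pseudocatenulatum",
)

#: nine SCFAs + three BCAAs, as measured in urine (mmol/g creatinine)
METABOLITES = (
    "acetic acid",
    "propionic acid",
    "butyric acid",
    "valeric acid",
    "caproic acid",
    "heptanoic acid",
    "isobutyric acid",
    "2-methylbutyric acid",
    "isovaleric acid",
    "valine",
    "leucine",
    "isoleucine",
)

_SCFAS = METABOLITES[:9]
_BCAAS = METABOLITES[9:]

AGE_RANGE = (7.0, 17.0)  # recruitment window, years
BMI_FLOOR = 10.0  # kg/m^2, guard against nonphysical draws


@dataclass(frozen=True)
class GroupSpec:
    """Demographic recipe for one study group.

    HbA1c (%) is present only for the T1D group; the other groups were
    not assayed.
    """

    name: str
    n: int
    male_fraction: float
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    hba1c_mean: float | None = None
    hba1c_sd: float | None = None

    def __post_init__(self) -> None:
        if self.name not in GROUPS:
            raise ValueError(f"group name must be one of {GROUPS}, got {self.name!r}")
        if self.n < 1:
            raise ValueError(f"group {self.name!r}: n must be >= 1, got {self.n}")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError(f"group {self.name!r}: male_fraction outside [0, 1]")
        for label, sd in (("age_sd", self.age_sd), ("bmi_sd", self.bmi_sd)):
            if sd < 0:
                raise ValueError(f"group {self.name!r}: {label} must be >= 0")
        has_hba1c = self.hba1c_mean is not None
        if has_hba1c != (self.name == "t1d"):
            raise ValueError(
                f"group {self.name!r}: HbA1c must be present iff the group is 't1d'"
            )
        if has_hba1c and (self.hba1c_sd is None or self.hba1c_sd < 0):
            raise ValueError(f"group {self.name!r}: hba1c_sd must be >= 0")


def default_study_design() -> list[GroupSpec]:
    """The study's demographic design: 40 controls, 40 T1D, 18 obese.

    Means and SDs are the published group characteristics; the control
    sex ratio (22 M / 17 F as printed) is kept as a fraction so it
    rescales to the group size of 40.
    """
    return [
        GroupSpec("control", 40, 22 / 39, 12.67, 2.34, 20.51, 3.59),
        GroupSpec("t1d", 40, 25 / 40, 12.65, 2.59, 22.15, 5.23, 7.09, 2.01),
        GroupSpec("obese", 18, 8 / 18, 13.33, 2.4, 32.46, 4.77),
    ]


@dataclass(frozen=True)
class EffectTemplate:
    """Multiplicative group effects injected into the generator.

    ``taxon_multipliers[(group, taxon)]`` scales the taxon's Dirichlet
    base weight; ``taxon_presence[(group, taxon)]`` is the Bernoulli
    detection probability; ``metabolite_multipliers[(group, analyte)]``
    scales the analyte's median; ``kidmed_shift[group]`` shifts the
    expected diet score in points. Control multipliers must all be one —
    controls define the baseline.
    """

    taxon_multipliers: dict[tuple[str, str], float]
    taxon_presence: dict[tuple[str, str], float]
    metabolite_multipliers: dict[tuple[str, str], float]
    kidmed_shift: dict[str, float]

    def __post_init__(self) -> None:
        for (g, t), m in self.taxon_multipliers.items():
            if m <= 0:
                raise ValueError(f"taxon multiplier for ({g!r}, {t!r}) must be > 0")
            if g == "control" and m != 1.0:
                raise ValueError(f"control taxon multipliers must be 1, got {m} for {t!r}")
        for (g, t), p in self.taxon_presence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"presence probability for ({g!r}, {t!r}) outside [0, 1]")
        for (g, a), m in self.metabolite_multipliers.items():
            if m <= 0:
                raise ValueError(f"metabolite multiplier for ({g!r}, {a!r}) must be > 0")
            if g == "control" and m != 1.0:
                raise ValueError(f"control metabolite multipliers must be 1, got {m} for {a!r}")

    def require_taxa(self, groups: list[str], taxa: tuple[str, ...] = TAXA) -> None:
        missing = [
            (g, t) for g in groups for t in taxa
            if (g, t) not in self.taxon_multipliers or (g, t) not in self.taxon_presence
        ]
        if missing:
            raise ValueError(f"effect template missing taxon entries: {missing}")

    def require_metabolites(
        self, groups: list[str], analytes: tuple[str, ...] = METABOLITES
    ) -> None:
        missing = [
            (g, a) for g in groups for a in analytes
            if (g, a) not in self.metabolite_multipliers
        ]
        if missing:
            raise ValueError(f"effect template missing metabolite entries: {missing}")


def null_effect_template() -> EffectTemplate:
    """No group effects: all multipliers one, presence 0.9, no score shift."""
    return EffectTemplate(
        taxon_multipliers={(g, t): 1.0 for g in GROUPS for t in TAXA},
        taxon_presence={(g, t): 0.9 for g in GROUPS for t in TAXA},
        metabolite_multipliers={(g, a): 1.0 for g in GROUPS for a in METABOLITES},
        kidmed_shift={g: 0.0 for g in GROUPS},
    )


def default_effect_template() -> EffectTemplate:
    """Directions reported by the study, with synthetic 2x / 0.5x magnitudes.

    Obesity: *infantis* and *breve* up, *bifidum* and *longum* subs.
    *longum* down, *bifidum* also detected less often (presence 0.9 ->
    0.6); valeric acid intermediate, BCAAs down; diet score +2. T1D:
    *pseudocatenulatum* and *adolescentis* mildly up (1.5x — the study
    describes the T1D microbiome shift as secondary to the obesity
    one); valeric, propionic, butyric and heptanoic acids strongly up,
    the remaining SCFAs mildly up.
    """
    t = null_effect_template()
    taxon_mult = dict(t.taxon_multipliers)
    taxon_mult.update({
        ("obese", "longum subs. infantis"): 2.0,
        ("obese", "breve"): 2.0,
        ("obese", "bifidum"): 0.5,
        ("obese", "longum subs. longum"): 0.5,
        ("t1d", "pseudocatenulatum"): 1.5,
        ("t1d", "adolescentis"): 1.5,
    })
    presence = dict(t.taxon_presence)
    presence[("obese", "bifidum")] = 0.6
    met_mult = dict(t.metabolite_multipliers)
    met_mult.update({
        ("t1d", "valeric acid"): 2.5,
        ("t1d", "propionic acid"): 2.0,
        ("t1d", "butyric acid"): 2.0,
        ("t1d", "heptanoic acid"): 2.0,
        ("t1d", "acetic acid"): 1.3,
        ("t1d", "caproic acid"): 1.3,
        ("t1d", "isobutyric acid"): 1.3,
        ("t1d", "2-methylbutyric acid"): 1.3,
        ("t1d", "isovaleric acid"): 1.3,
        ("obese", "valeric acid"): 1.5,
        ("obese", "valine"): 0.5,
        ("obese", "isoleucine"): 0.5,
        ("obese", "leucine"): 0.7,
    })
    return EffectTemplate(
        taxon_multipliers=taxon_mult,
        taxon_presence=presence,
        metabolite_multipliers=met_mult,
        kidmed_shift={"control": 0.0, "t1d": 0.0, "obese": 2.0},
    )


@dataclass
class Cohort:
    """The four linked tables of one synthetic cohort."""

    participants: pd.DataFrame
    microbiome: pd.DataFrame
    metabolites: pd.DataFrame
    kidmed: pd.DataFrame


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Rejection-sampled truncated normal; falls back to clipping only in
    the degenerate sd=0 case."""
    if sd == 0:
        return np.clip(np.full(n, mean), lo, hi)
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_participants(
    specs: list[GroupSpec], seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw the participants table: id, group, sex, age, bmi, hba1c.

    Ages are normal truncated to the 7-17 y recruitment window; BMI is
    normal truncated below at 10 kg/m^2; sex is Bernoulli with the
    group's male fraction. HbA1c is drawn only where the spec carries
    it (NaN elsewhere).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    frames = []
    counter = 1
    for spec in specs:
        age = _truncated_normal(rng, spec.age_mean, spec.age_sd, *AGE_RANGE, spec.n)
        bmi = _truncated_normal(rng, spec.bmi_mean, spec.bmi_sd, BMI_FLOOR, np.inf, spec.n)
        sex = np.where(rng.random(spec.n) < spec.male_fraction, "M", "F")
        if spec.hba1c_mean is not None:
            hba1c = _truncated_normal(rng, spec.hba1c_mean, spec.hba1c_sd, 0.0, np.inf, spec.n)
        else:
            hba1c = np.full(spec.n, np.nan)
        frames.append(pd.DataFrame({
            "id": [f"P{counter + i:03d}" for i in range(spec.n)],
            "group": spec.name,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "hba1c": hba1c,
        }))
        counter += spec.n
    return pd.concat(frames, ignore_index=True)


#: baseline Dirichlet composition of the eight taxa in controls
_BASE_WEIGHTS = {
    "longum subs. longum": 0.25,
    "adolescentis": 0.20,
    "bifidum": 0.15,
    "pseudocatenulatum": 0.12,
    "breve": 0.10,
    "longum subs. infantis": 0.08,
    "animalis subs. lactis": 0.06,
    "animalis subs. animalis": 0.04,
}

#: Dirichlet concentration; ~15 gives the broad, overdispersed spread of
#: real compositional abundance data at these sample sizes
_CONCENTRATION = 15.0


def generate_microbiome(
    participants: pd.DataFrame,
    template: EffectTemplate,
    seed: int | np.random.Generator,
    *,
    base_weights: dict[str, float] | None = None,
    concentration: float = _CONCENTRATION,
) -> pd.DataFrame:
    """Draw per-participant relative abundances of the eight taxa.

    Per participant: a Bernoulli presence indicator per taxon, then
    gamma draws with shape ``concentration * base_weight * multiplier``
    for the present taxa, renormalised to sum to one. If every taxon is
    absent, the taxon with the largest group weight is forced present so
    the row remains a composition.
    """
    base_weights = dict(_BASE_WEIGHTS) if base_weights is None else base_weights
    if set(base_weights) != set(TAXA):
        raise ValueError("base_weights must cover exactly the eight panel taxa")
    groups = sorted(participants["group"].unique())
    template.require_taxa(groups)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    taxa = list(TAXA)
    rows = np.empty((len(participants), len(taxa)))
    for i, (_, p) in enumerate(participants.iterrows()):
        g = p["group"]
        alpha = np.array([
            concentration * base_weights[t] * template.taxon_multipliers[(g, t)]
            for t in taxa
        ])
        present = rng.random(len(taxa)) < np.array(
            [template.taxon_presence[(g, t)] for t in taxa]
        )
        if not present.any():
            present[int(np.argmax(alpha))] = True
        draw = np.zeros(len(taxa))
        draw[present] = rng.gamma(shape=alpha[present], scale=1.0)
        if draw.sum() == 0:  # pathological gamma underflow
            draw[present] = alpha[present]
        rows[i] = draw / draw.sum()
    out = pd.DataFrame(rows, columns=taxa)
    out.insert(0, "id", participants["id"].to_numpy())
    return out


#: baseline urinary medians, mmol/g creatinine (acetate dominates; minor
#: SCFAs and BCAAs at the tenth-of-a-mmol scale typical of children)
_BASE_MEDIANS = {
    "acetic acid": 2.0,
    "propionic acid": 0.30,
    "butyric acid": 0.20,
    "valeric acid": 0.05,
    "caproic acid": 0.03,
    "heptanoic acid": 0.02,
    "isobutyric acid": 0.10,
    "2-methylbutyric acid": 0.08,
    "isovaleric acid": 0.12,
    "valine": 0.25,
    "leucine": 0.15,
    "isoleucine": 0.10,
}

#: log-scale SD of the analyte distributions (CV ~= 65%)
_LOG_SIGMA = 0.6

#: urinary creatinine, g/L, log-normal around ~1 g/L
_CREATININE_MEDIAN = 1.0
_CREATININE_SIGMA = 0.4


def normalize_to_creatinine(concentration: float, creatinine: float):
    """Express a urinary concentration (mmol/L) per gram of creatinine.

    Dividing by the creatinine concentration (g/L) corrects for urine
    dilution; the result is mmol/g creatinine.
    """
    creat = np.asarray(creatinine, dtype=float)
    if np.any(creat <= 0):
        raise ValueError(f"creatinine concentration must be > 0 g/L, got {creatinine}")
    conc = np.asarray(concentration, dtype=float)
    out = conc / creat
    return float(out) if out.ndim == 0 else out


def generate_metabolites(
    participants: pd.DataFrame,
    template: EffectTemplate,
    seed: int | np.random.Generator,
    *,
    base_medians: dict[str, float] | None = None,
    log_sigma: float = _LOG_SIGMA,
) -> pd.DataFrame:
    """Draw the twelve urinary analytes in mmol/g creatinine.

    Raw concentrations are log-normal around group-scaled medians; each
    participant gets a log-normal creatinine level and the table is
    creatinine-normalised, mimicking the dilution correction applied to
    spot urine samples.
    """
    base_medians = dict(_BASE_MEDIANS) if base_medians is None else base_medians
    if set(base_medians) != set(METABOLITES):
        raise ValueError("base_medians must cover exactly the twelve analytes")
    groups = sorted(participants["group"].unique())
    template.require_metabolites(groups)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = len(participants)
    creatinine = _CREATININE_MEDIAN * np.exp(rng.normal(0.0, _CREATININE_SIGMA, size=n))
    data = {}
    mult = np.empty(n)
    for analyte in METABOLITES:
        for i, g in enumerate(participants["group"]):
            mult[i] = template.metabolite_multipliers[(g, analyte)]
        # median concentration scales with creatinine so the normalised
        # value stays centred on the group median
        raw = (
            base_medians[analyte] * mult * creatinine
            * np.exp(rng.normal(0.0, log_sigma, size=n))
        )
        data[analyte] = normalize_to_creatinine(raw, creatinine)
    out = pd.DataFrame(data)
    out.insert(0, "id", participants["id"].to_numpy())
    return out


#: baseline yes-probability per item (positive items ~0.5, negative ~0.3)
_KIDMED_BASE_P_POS = 0.5
_KIDMED_BASE_P_NEG = 0.3


def generate_kidmed(
    participants: pd.DataFrame,
    template: EffectTemplate,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Draw item-level KIDMED answers and score them.

    A group's ``kidmed_shift`` (in score points) is spread over the
    twelve positive items as a uniform increase in their yes
    probabilities, so expected group scores differ by the shift. Scores
    are computed through :func:`bifidopanel.kidmed.score_kidmed`.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    items = _kidmed.default_items()
    pos_items = [it for it in items if it.polarity == +1]

    records = []
    for _, p in participants.iterrows():
        shift = template.kidmed_shift.get(p["group"], 0.0)
        answers = {}
        for it in items:
            base = _KIDMED_BASE_P_POS if it.polarity == +1 else _KIDMED_BASE_P_NEG
            prob = base + (shift / len(pos_items) if it.polarity == +1 else 0.0)
            answers[it.item_id] = bool(rng.random() < np.clip(prob, 0.0, 1.0))
        scored = _kidmed.score_kidmed(
            _kidmed.KidmedResponses(p["id"], answers), items
        )
        rec = {"id": p["id"]}
        rec.update({f"q{i}": answers[i] for i in range(1, 17)})
        rec["score"] = scored.score
        rec["category"] = scored.category
        records.append(rec)
    return pd.DataFrame(records)


def generate_cohort(
    specs: list[GroupSpec] | None = None,
    template: EffectTemplate | None = None,
    seed: int | np.random.Generator = 0,
) -> Cohort:
    """Generate a full cohort (participants, microbiome, metabolites,
    KIDMED) from one seed; defaults reproduce the study design and the
    reported effect directions."""
    specs = default_study_design() if specs is None else specs
    template = default_effect_template() if template is None else template
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    participants = generate_participants(specs, rng)
    return Cohort(
        participants=participants,
        microbiome=generate_microbiome(participants, template, rng),
        metabolites=generate_metabolites(participants, template, rng),
        kidmed=generate_kidmed(participants, template, rng),
    )
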