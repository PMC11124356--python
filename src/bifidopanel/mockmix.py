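"""Mock-community spike designs and the flow-cytometry error budget.

A quantitative profiling assay for *Bifidobacterium* (sub)species is
validated against gravimetric mock communities: pure freeze-dried
cultures of known potency (Total Fluorescent Units per gram, measured by
fluorescence flow cytometry) are blended at known weights, the relative
abundance of every strain is predicted from ``weight x potency``, and
the assay's measured profile is compared with the prediction by the mean
absolute error (MAE) over all mix-by-strain pairs.

Because the potencies themselves carry flow-cytometry measurement noise
— a reproducibility standard deviation ``S_R`` on the log10(TFU) scale —
the expected disagreement can be budgeted before any assay is run:

* relative error of a single potency:  ``|1 - 10**S_R|``
* absolute error of a predicted fraction in an N-component blend:
  ``relative_error / (N - 1)``

With the measured ``S_R = 0.10`` this gives ~26% relative and ~5.2%
absolute for a six-strain blend; the ISO 19344 benchmark ``S_R = 0.134``
gives ~7.2%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StrainCulture", "MixComponent", "MixDesign", "AbundanceProfile",
    "ErrorBudget", "ValidationReport", "build_spike_designs",
    "predict_profile", "ffc_relative_error", "predicted_absolute_error",
    "simulate_ffc_potencies", "mean_absolute_error", "default_strain_panel",
]

#: absolute tolerance for a set of fractions to count as summing to one
_SUM_ATOL = 1e-9


@dataclass(frozen=True)
class StrainCulture:
    """A pure freeze-dried culture with a flow-cytometry potency.

    Parameters
    ----------
    species_label
        (Sub)species name, e.g. ``"longum subs. infantis"``; unique
        within a panel.
    strain_code
        Manufacturer strain code, e.g. ``"BI02"``.
    potency
        Viable-cell potency in TFU per gram; strictly positive.
    """

    species_label: str
    strain_code: str
    potency: float

    def __post_init__(self) -> None:
        if not self.potency > 0:
            raise ValueError(
                f"potency must be > 0 TFU/g, got {self.potency!r} "
                f"for strain {self.species_label!r}"
            )


@dataclass(frozen=True)
class MixComponent:
    """One weighed component of a mock blend."""

    strain: StrainCulture
    weight: float  # grams

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError(
                f"component weight must be > 0 g, got {self.weight!r} "
                f"for strain {self.strain.species_label!r}"
            )


@dataclass(frozen=True)
class MixDesign:
    """A gravimetric blend of pure cultures.

    ``total_weight`` must equal the component sum (relative tolerance
    1e-9) and all strains must be distinct.
    """

    mix_id: str
    components: tuple[MixComponent, ...]
    total_weight: float
    spiked_strain: str | None = None  # species_label of the 5x component

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        labels = [c.strain.species_label for c in self.components]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate strains in mix {self.mix_id!r}: {sorted(dupes)}")
        s = sum(c.weight for c in self.components)
        if not math.isclose(s, self.total_weight, rel_tol=1e-9):
            raise ValueError(
                f"mix {self.mix_id!r}: component weights sum to {s} g but "
                f"total_weight is {self.total_weight} g "
                f"(discrepancy {s - self.total_weight:+g} g)"
            )

    @property
    def strains(self) -> tuple[str, ...]:
        return tuple(c.strain.species_label for c in self.components)

    def weights(self) -> dict[str, float]:
        return {c.strain.species_label: c.weight for c in self.components}


@dataclass(frozen=True)
class AbundanceProfile:
    """Per-taxon relative abundances of one sample; fractions sum to one."""

    sample_id: str
    abundances: dict[str, float]

    def __post_init__(self) -> None:
        for taxon, frac in self.abundances.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"{self.sample_id!r}: fraction for {taxon!r} is {frac}, "
                    "outside [0, 1]"
                )
        total = sum(self.abundances.values())
        if abs(total - 1.0) > _SUM_ATOL:
            raise ValueError(
                f"{self.sample_id!r}: fractions sum to {total}, not 1"
            )

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.abundances)

    def as_series(self) -> pd.Series:
        return pd.Series(self.abundances, name=self.sample_id)


def ffc_relative_error(s_r: float) -> float:
    """Relative error of a single potency reading.

    A reproducibility standard deviation ``s_r`` on the log10(TFU) scale
    means a one-sigma reading is off by a factor ``10**s_r``; the
    corresponding relative error is ``|1 - 10**s_r|`` (0.2589, ~26%, for
    ``s_r = 0.10``).
    """
    if s_r < 0:
        raise ValueError(f"s_r must be >= 0 (log10 units), got {s_r}")
    return abs(1.0 - 10.0 ** s_r)


def predicted_absolute_error(s_r: float, n_components: int) -> float:
    """Expected absolute error of a predicted fraction in an N-component mix.

    One mis-measured potency in a blend of ``n_components`` perturbs its
    own fraction against the remaining ``n_components - 1``; the budget
    is ``ffc_relative_error(s_r) / (n_components - 1)`` — ~5.2% for
    ``(0.10, 6)`` and ~7.2% for ``(0.134, 6)``.
    """
    n_components = int(n_components)
    if n_components < 2:
        raise ValueError(f"n_components must be >= 2, got {n_components}")
    return ffc_relative_error(s_r) / (n_components - 1)


@dataclass(frozen=True)
class ErrorBudget:
    """Precision bound for predicted fractions of an N-component blend."""

    s_r: float
    n_components: int
    relative_error: float = field(init=False)
    absolute_percent_error: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "relative_error", ffc_relative_error(self.s_r))
        object.__setattr__(
            self,
            "absolute_percent_error",
            predicted_absolute_error(self.s_r, self.n_components),
        )


def default_strain_panel() -> list[StrainCulture]:
    """The six-strain validation panel.

    Potencies are representative lyophilised-culture values (order 1e10
    TFU/g); the published design states weights, not potencies, so these
    defaults matter only through their ratios.
    """
    return [
        StrainCulture("adolescentis", "BA02", 2.0e10),
        StrainCulture("animalis subs. lactis", "BS01", 3.5e10),
        StrainCulture("bifidum", "BB10", 1.5e10),
        StrainCulture("breve", "BR03", 2.5e10),
        StrainCulture("longum subs. infantis", "BI02", 1.8e10),
        StrainCulture("longum subs. longum", "BL03", 2.2e10),
    ]


def build_spike_designs(
    strains: list[StrainCulture],
    total_weight: float = 120.0,
    spike_weight: float = 100.0,
    base_weight: float = 4.0,
) -> list[MixDesign]:
    """Build the equal-ratio mix plus one 5x spike mix per strain.

    Mix 1 blends every strain at ``total_weight / len(strains)`` grams;
    each subsequent mix raises one strain to ``spike_weight`` and drops
    all others to ``base_weight``. The default geometry (120 g total,
    100 g spike, 4 g base for six strains) gives seven mixes of 120 g.

    Raises
    ------
    ValueError
        If the spike geometry does not sum to ``total_weight``, fewer
        than two strains are given, or strain labels repeat.
    """
    if len(strains) < 2:
        raise ValueError("at least 2 strains are required for a mix design")
    labels = [s.species_label for s in strains]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate strain labels in panel: {labels}")
    expected = spike_weight + (len(strains) - 1) * base_weight
    if not math.isclose(expected, total_weight, rel_tol=1e-9):
        raise ValueError(
            f"spike geometry inconsistent: spike {spike_weight} g + "
            f"{len(strains) - 1} x base {base_weight} g = {expected} g, "
            f"but total_weight is {total_weight} g "
            f"(discrepancy {expected - total_weight:+g} g)"
        )

    equal_w = total_weight / len(strains)
    designs = [
        MixDesign(
            mix_id="mix1",
            components=tuple(MixComponent(s, equal_w) for s in strains),
            total_weight=total_weight,
        )
    ]
    for i, spiked in enumerate(strains):
        comps = tuple(
            MixComponent(s, spike_weight if s is spiked else base_weight)
            for s in strains
        )
        designs.append(
            MixDesign(
                mix_id=f"mix{i + 2}",
                components=comps,
                total_weight=total_weight,
                spiked_strain=spiked.species_label,
            )
        )
    return designs


def predict_profile(mix: MixDesign, potencies: dict[str, float]) -> AbundanceProfile:
    """Predict the relative-abundance profile of a blend from potencies.

    Each strain contributes ``weight_i * potency_i`` fluorescent units;
    fractions are these contributions normalised to one. The prediction
    is invariant to rescaling all potencies by a common factor.
    """
    missing = [l for l in mix.strains if l not in potencies]
    if missing:
        raise ValueError(
            f"mix {mix.mix_id!r}: no potency supplied for strain(s) {missing}"
        )
    units = {}
    for comp in mix.components:
        label = comp.strain.species_label
        pot = potencies[label]
        if not pot > 0:
            raise ValueError(
                f"potency for {label!r} must be > 0 TFU/g, got {pot}"
            )
        units[label] = comp.weight * pot
    total = sum(units.values())
    return AbundanceProfile(
        sample_id=mix.mix_id,
        abundances={l: u / total for l, u in units.items()},
    )


def simulate_ffc_potencies(
    potencies: dict[str, float],
    s_r: float,
    seed: int | np.random.Generator,
) -> dict[str, float]:
    """Draw one noisy flow-cytometry reading of each potency.

    Each potency is multiplied by ``10**eps`` with ``eps`` i.i.d. normal,
    zero mean, standard deviation ``s_r`` on the log10 scale — the
    marginal reproducibility model of the FFC method. Deterministic
    given ``seed``.
    """
    if s_r < 0:
        raise ValueError(f"s_r must be >= 0 (log10 units), got {s_r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = list(potencies)
    eps = rng.normal(0.0, s_r, size=len(labels)) if s_r > 0 else np.zeros(len(labels))
    return {l: potencies[l] * 10.0 ** e for l, e in zip(labels, eps)}


@dataclass(frozen=True)
class ValidationReport:
    """Predicted-vs-observed agreement of a set of profiles.

    ``pairs`` holds one row per (mix, taxon) combination with columns
    ``mix_id, taxon, predicted, observed, absolute_difference``; ``mae``
    is the arithmetic mean of the absolute differences pooled over all
    pairs; ``within_budget`` compares ``mae`` against the budget's
    absolute error when a budget is attached.
    """

    pairs: pd.DataFrame
    mae: float
    budget: ErrorBudget | None = None
    within_budget: bool | None = None

    def summary(self) -> str:
        lines = [
            f"validation over {self.pairs['mix_id'].nunique()} mixes x "
            f"{self.pairs['taxon'].nunique()} taxa "
            f"({len(self.pairs)} predicted/observed pairs)",
            f"mean absolute error: {100 * self.mae:.2f} percentage points",
        ]
        if self.budget is not None:
            lines.append(
                f"error budget (S_R={self.budget.s_r}, "
                f"N={self.budget.n_components}): relative "
                f"{100 * self.budget.relative_error:.1f}%, absolute "
                f"{100 * self.budget.absolute_percent_error:.1f}%"
            )
            lines.append(
                "MAE within budget" if self.within_budget else "MAE exceeds budget"
            )
        return "\n".join(lines)


def mean_absolute_error(
    predicted: list[AbundanceProfile],
    observed: list[AbundanceProfile],
    budget: ErrorBudget | None = None,
) -> ValidationReport:
    """Score predicted against observed profiles by pooled MAE.

    Both lists must cover the same sample ids and, per sample, the same
    taxon sets; every (mix, taxon) pair enters the mean exactly once.
    """
    pred_by_id = {p.sample_id: p for p in predicted}
    obs_by_id = {o.sample_id: o for o in observed}
    if set(pred_by_id) != set(obs_by_id):
        only_p = sorted(set(pred_by_id) - set(obs_by_id))
        only_o = sorted(set(obs_by_id) - set(pred_by_id))
        raise ValueError(
            f"mix ids differ: only in predicted {only_p}, only in observed {only_o}"
        )
    if len(pred_by_id) != len(predicted):
        raise ValueError("duplicate sample ids in predicted profiles")

    rows = []
    for mix_id in pred_by_id:
        p, o = pred_by_id[mix_id], obs_by_id[mix_id]
        if p.taxa != o.taxa:
            raise ValueError(
                f"mix {mix_id!r}: taxon sets differ "
                f"(predicted-only {sorted(p.taxa - o.taxa)}, "
                f"observed-only {sorted(o.taxa - p.taxa)})"
            )
        for taxon in sorted(p.taxa):
            pv, ov = p.abundances[taxon], o.abundances[taxon]
            rows.append((mix_id, taxon, pv, ov, abs(pv - ov)))
    pairs = pd.DataFrame(
        rows, columns=["mix_id", "taxon", "predicted", "observed", "absolute_difference"]
    )
    mae = float(pairs["absolute_difference"].mean())
    within = None if budget is None else bool(mae <= budget.absolute_percent_error)
    return ValidationReport(pairs=pairs, mae=mae, budget=budget, within_budget=within)
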