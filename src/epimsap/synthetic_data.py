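"""Synthetic-data generators for the hypomethylation screening pipeline.

Every input the downstream statistics consume can be produced here: paired
HpaII/MspI MSAP band matrices driven by latent per-locus CCGG methylation
states, binomial dose-response tables on a declining logistic, long-format
seed/line trait tables with a shared latent "desaturation" factor inducing the
fatty-acid trade-offs, and the population pedigree ledger (E1 plants, E2 seed
accessions, E2 plants).

All randomness flows through one ``numpy.random.Generator`` seeded from the
spec's ``rng_seed``; draws happen in a fixed documented order (founder states,
per-line treatment efficacy, per-sample noise), so identical specs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping

import numpy as np
import pandas as pd

from .dose_response import logistic_decline
from .msap_core import MSAPMatrix

__all__ = [
    "MethylationLocusState",
    "HPAII_BAND",
    "MSPI_BAND",
    "PopulationSpec",
    "DoseResponseSpec",
    "TraitGroupParams",
    "TraitSpec",
    "simulate_msap_population",
    "simulate_dose_response",
    "simulate_traits",
    "build_population_pedigree",
    "study_cohort_spec",
    "default_trait_spec",
    "study_lines_metadata",
]


class MethylationLocusState(IntEnum):
    """Methylation class of one CCGG site, as resolved by HpaII/MspI digestion.

    HpaII is blocked by methylation of either cytosine; MspI cuts through
    internal-cytosine (CG-context) methylation but is blocked by
    external-cytosine (CHG-context) methylation.  A band is scored when the
    enzyme cuts.
    """

    UNMETHYLATED = 0      # CCGG        -> HpaII band, MspI band
    CG_INTERNAL = 1       # C(5mC)GG    -> no HpaII band, MspI band
    CHG_EXTERNAL = 2      # (5mC)CGG    -> neither band
    FULL = 3              # both methylated -> neither band


# Band presence (1 = fragment amplified) as a pure function of locus state,
# indexed by MethylationLocusState value.
HPAII_BAND = np.array([1, 0, 0, 0], dtype=np.int8)
MSPI_BAND = np.array([1, 1, 0, 0], dtype=np.int8)

_N_STATES = 4


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")


@dataclass(frozen=True)
class PopulationSpec:
    """Design of a simulated control + 5-AzaC-treated MSAP cohort.

    ``state_frequencies`` is the probability vector over the four locus states
    (unmethylated, internal-CG, external-CHG, fully methylated) from which
    founder epigenotypes are drawn.  ``p_demeth`` is the per-locus probability
    that a methylated locus reverts to unmethylated in the founder of an
    *effectively treated* line; ``n_effective_treated`` controls in how many
    treated lines the chemical treatment actually took effect (``None`` = all
    of them), mirroring the stochastic efficacy of the mutagen.
    ``p_epi_noise`` is the per-sample, per-locus probability that a locus
    state is resampled from the base frequencies (within-line variability).
    """

    n_control_lines: int = 4
    n_treated_lines: int = 10
    n_samples_per_line: int = 10
    n_loci: int = 500
    state_frequencies: tuple[float, float, float, float] = (0.5, 0.3, 0.1, 0.1)
    p_demeth: float = 1.0
    p_epi_noise: float = 0.02
    n_effective_treated: int | None = None
    control_generations: tuple[str, ...] | None = None
    treated_generations: tuple[str, ...] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control_lines", "n_treated_lines",
                     "n_samples_per_line", "n_loci"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        freqs = np.asarray(self.state_frequencies, dtype=float)
        if freqs.shape != (_N_STATES,) or np.any(freqs < 0) or np.any(freqs > 1):
            raise ValueError(
                "state_frequencies must be 4 probabilities in [0, 1], got "
                f"{self.state_frequencies!r}"
            )
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"state_frequencies must sum to 1, got sum {freqs.sum()!r}"
            )
        _check_prob("p_demeth", self.p_demeth)
        _check_prob("p_epi_noise", self.p_epi_noise)
        if self.n_effective_treated is not None and not (
            0 <= self.n_effective_treated <= self.n_treated_lines
        ):
            raise ValueError(
                "n_effective_treated must lie in [0, n_treated_lines]"
            )
        for name, n in (("control_generations", self.n_control_lines),
                        ("treated_generations", self.n_treated_lines)):
            labels = getattr(self, name)
            if labels is not None and len(labels) != n:
                raise ValueError(f"{name} must have one label per line")


def study_cohort_spec(rng_seed: int = 0, **overrides) -> PopulationSpec:
    """The 14-line sampling design used for MSAP profiling in the study.

    Two S2 and two S3 untreated control lines, five E2 and five E3 treated
    lines, ten seedlings per line; treatment effective in four of the ten
    treated lines.
    """
    kwargs: dict = dict(
        n_control_lines=4,
        n_treated_lines=10,
        n_samples_per_line=10,
        n_loci=500,
        n_effective_treated=4,
        control_generations=("S2", "S2", "S3", "S3"),
        treated_generations=("E2",) * 5 + ("E3",) * 5,
        rng_seed=rng_seed,
    )
    kwargs.update(overrides)
    return PopulationSpec(**kwargs)


def _line_labels(spec: PopulationSpec) -> tuple[list[str], list[str], list[str]]:
    ctrl_gen = list(spec.control_generations or ["S2"] * spec.n_control_lines)
    trt_gen = list(spec.treated_generations or ["E2"] * spec.n_treated_lines)
    ctrl_ids = [f"ctrl_{i + 1:02d}" for i in range(spec.n_control_lines)]
    trt_ids = [f"aza_{i + 1:02d}" for i in range(spec.n_treated_lines)]
    return ctrl_ids, trt_ids, ctrl_gen + trt_gen


def simulate_msap_population(
    spec: PopulationSpec,
) -> tuple[MSAPMatrix, MSAPMatrix, pd.DataFrame]:
    """Simulate paired HpaII/MspI band matrices plus true line labels.

    For each line a founder state vector is drawn from
    ``spec.state_frequencies``.  In effectively treated lines every methylated
    founder locus reverts to unmethylated with probability ``p_demeth``.
    Each sampled seedling then carries the founder epigenotype with
    independent per-locus resampling noise at rate ``p_epi_noise``; the same
    realised state vector drives both enzyme digests of that seedling, so the
    two matrices are two read-outs of one latent epigenotype.

    Returns ``(hpaii, mspi, lines)`` where ``lines`` has one row per line
    with columns ``line_id, generation, treatment, truly_hypomethylated``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    freqs = np.asarray(spec.state_frequencies, dtype=float)
    ctrl_ids, trt_ids, generations = _line_labels(spec)
    line_ids = ctrl_ids + trt_ids
    treatments = ["control"] * len(ctrl_ids) + ["treated"] * len(trt_ids)

    # Draw order: (1) founder states for every line, (2) treatment efficacy,
    # (3) per-line demethylation masks, (4) per-sample noise.
    founders = {
        lid: rng.choice(_N_STATES, size=spec.n_loci, p=freqs)
        for lid in line_ids
    }
    if spec.n_effective_treated is None:
        effective = set(trt_ids)
    else:
        effective = set(
            rng.choice(trt_ids, size=spec.n_effective_treated, replace=False)
        )
    for lid in trt_ids:
        if lid in effective and spec.p_demeth > 0:
            st = founders[lid]
            revert = (st != MethylationLocusState.UNMETHYLATED) & (
                rng.random(spec.n_loci) < spec.p_demeth
            )
            st[revert] = MethylationLocusState.UNMETHYLATED

    sample_ids, sample_lines, sample_gens = [], [], []
    hpa_rows, msp_rows = [], []
    for lid, gen in zip(line_ids, generations):
        for k in range(spec.n_samples_per_line):
            state = founders[lid].copy()
            if spec.p_epi_noise > 0:
                noisy = rng.random(spec.n_loci) < spec.p_epi_noise
                n_noisy = int(noisy.sum())
                if n_noisy:
                    state[noisy] = rng.choice(_N_STATES, size=n_noisy, p=freqs)
            sample_ids.append(f"{lid}_s{k + 1:02d}")
            sample_lines.append(lid)
            sample_gens.append(gen)
            hpa_rows.append(HPAII_BAND[state])
            msp_rows.append(MSPI_BAND[state])

    locus_ids = [f"L{j + 1:04d}" for j in range(spec.n_loci)]

    def _matrix(rows: list[np.ndarray], enzyme: str) -> MSAPMatrix:
        values = pd.DataFrame(
            np.vstack(rows).astype(float), index=sample_ids, columns=locus_ids
        )
        return MSAPMatrix(
            values=values,
            line_ids=pd.Series(sample_lines, index=sample_ids),
            generations=pd.Series(sample_gens, index=sample_ids),
            enzyme=enzyme,
        )

    lines = pd.DataFrame(
        {
            "line_id": line_ids,
            "generation": generations,
            "treatment": treatments,
            "truly_hypomethylated": [lid in effective for lid in line_ids],
        }
    )
    return _matrix(hpa_rows, "HpaII"), _matrix(msp_rows, "MspI"), lines


@dataclass(frozen=True)
class DoseResponseSpec:
    """Binomial sampling design around a declining constrained logistic.

    Defaults follow the study's germination-tray design: water control plus
    five 5-AzaC concentrations, four replicate trays of 100 seedlings each,
    and a survival-type curve with lower asymptote 40%, rate 3 and midpoint
    0.32 mM.
    """

    doses: tuple[float, ...] = (0.0, 0.01, 0.1, 0.5, 1.0, 1.5)
    reps_per_dose: int = 4
    n_per_rep: int = 100
    true_params: Mapping[str, float] = field(
        default_factory=lambda: {"A": 40.0, "b": 3.0, "m": 0.32}
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        if doses.size < 2 or np.any(doses < 0):
            raise ValueError("doses must be >= 2 non-negative concentrations")
        if 0.0 not in doses:
            raise ValueError("doses must include the 0 (control) concentration")
        if self.reps_per_dose < 1 or self.n_per_rep < 1:
            raise ValueError("reps_per_dose and n_per_rep must be positive")
        p = dict(self.true_params)
        if not {"A", "b", "m"} <= p.keys():
            raise ValueError("true_params must provide A, b and m")
        if not (0.0 <= p["A"] <= 100.0):
            raise ValueError(f"lower asymptote A must lie in [0, 100], got {p['A']}")
        if p["m"] <= 0 or p["b"] <= 0:
            raise ValueError("rate b and midpoint m must be positive")


def simulate_dose_response(spec: DoseResponseSpec) -> pd.DataFrame:
    """Draw replicate binomial counts from the constrained logistic.

    At each dose the expected response percentage is
    ``y(x) = A + (100 - A) / (1 + (x/m)^b)`` (100% at dose 0, floor A), and
    ``responders ~ Binomial(n_per_rep, y/100)`` independently per replicate.
    """
    p = dict(spec.true_params)
    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    for dose in spec.doses:
        y = float(logistic_decline(dose, p["A"], p["b"], p["m"]))
        if not (0.0 <= y <= 100.0):
            raise ValueError(
                f"expected response {y} at dose {dose} outside [0, 100]"
            )
        responders = rng.binomial(spec.n_per_rep, y / 100.0, size=spec.reps_per_dose)
        for rep, r in enumerate(responders, start=1):
            rows.append((dose, rep, int(r), spec.n_per_rep))
    return pd.DataFrame(rows, columns=["dose", "rep", "responders", "total"])


@dataclass(frozen=True)
class TraitGroupParams:
    """Mean and variance components of one trait in one treatment group."""

    mean: float
    between_line_var: float
    within_line_var: float

    def __post_init__(self) -> None:
        if self.between_line_var < 0 or self.within_line_var < 0:
            raise ValueError("variance components must be non-negative")


#: Traits treated as fatty-acid fractions (loaded on the latent factor).
FATTY_ACID_TRAITS = ("palmitic_pct", "linoleic_pct", "erucic_pct")

#: Standardised loadings of each fatty acid on the latent desaturation factor.
#: The single-factor solution l_i with r_ij = l_i * l_j reproducing the
#: observed line-mean correlations (erucic:linoleic -0.88, palmitic:linoleic
#: +0.75, palmitic:erucic -0.74).
DEFAULT_LATENT_LOADINGS: dict[str, float] = {
    "palmitic_pct": 0.794,
    "linoleic_pct": 0.944,
    "erucic_pct": -0.932,
}

_TRAIT_UNITS = {
    "seed_area_mm2": "mm^2",
    "oil_pct": "% dry matter",
    "protein_pct": "% dry matter",
    "palmitic_pct": "% of total oil",
    "linoleic_pct": "% of total oil",
    "erucic_pct": "% of total oil",
}


@dataclass(frozen=True)
class TraitSpec:
    """Per-trait, per-group generating parameters for seed/line traits.

    ``traits`` maps trait name -> {"control": TraitGroupParams,
    "treated": TraitGroupParams}.  Fatty-acid traits additionally load on a
    per-line latent desaturation factor; ``latent_desaturation_effect``
    scales the standardised loadings (0 switches the correlation off, 1 gives
    the calibrated erucic/linoleic/palmitic correlation structure).
    """

    traits: Mapping[str, Mapping[str, TraitGroupParams]]
    latent_loadings: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_LOADINGS)
    )
    latent_desaturation_effect: float = 1.0
    n_samples_per_line: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for trait, groups in self.traits.items():
            if not {"control", "treated"} <= set(groups):
                raise ValueError(
                    f"trait {trait!r} needs 'control' and 'treated' parameters"
                )
        for trait, loading in self.latent_loadings.items():
            eff = abs(loading * self.latent_desaturation_effect)
            if eff > 1.0:
                raise ValueError(
                    f"scaled latent loading for {trait!r} exceeds 1 ({eff:.3f})"
                )
        oil = self.traits.get("oil_pct")
        protein = self.traits.get("protein_pct")
        if oil is not None and protein is not None:
            for grp in ("control", "treated"):
                total = oil[grp].mean + protein[grp].mean
                if total > 100.0:
                    raise ValueError(
                        f"oil + protein mean exceeds 100% in {grp} group ({total})"
                    )
        if self.n_samples_per_line < 1:
            raise ValueError("n_samples_per_line must be positive")


def default_trait_spec(rng_seed: int = 0,
                       latent_desaturation_effect: float = 1.0) -> TraitSpec:
    """Trait parameters calibrated to the reported group summaries.

    Seed-area means/components and oil/protein means are the printed values
    (control 48.9% oil / 23.4% protein vs treated 43.1% / 27.2%; seed area
    0.14 mm^2 smaller in treated lines with between/within-line variances
    0.125/0.122 vs 0.009/0.083).  Fatty-acid means are the E3/S3 group means;
    their dispersions are unpublished, so realistic magnitudes (treated lines
    roughly twice as variable) are used.
    """
    g = TraitGroupParams
    traits = {
        "seed_area_mm2": {"control": g(2.60, 0.009, 0.083),
                          "treated": g(2.46, 0.125, 0.122)},
        "oil_pct": {"control": g(48.9, 0.5, 1.0),
                    "treated": g(43.1, 3.0, 1.0)},
        "protein_pct": {"control": g(23.4, 0.3, 0.8),
                        "treated": g(27.2, 2.0, 0.8)},
        "palmitic_pct": {"control": g(3.15, 0.0225, 0.002),
                         "treated": g(3.24, 0.09, 0.002)},
        "linoleic_pct": {"control": g(18.82, 0.64, 0.05),
                         "treated": g(19.45, 2.56, 0.05)},
        "erucic_pct": {"control": g(57.56, 4.0, 0.2),
                       "treated": g(54.19, 16.0, 0.2)},
    }
    return TraitSpec(
        traits=traits,
        latent_desaturation_effect=latent_desaturation_effect,
        rng_seed=rng_seed,
    )


def study_lines_metadata(n_control: int = 30, n_treated: int = 100) -> pd.DataFrame:
    """Line metadata for the seed-trait screen (100 E2 lines, 30 S2 controls)."""
    rows = [(f"s2_{i + 1:03d}", "S2", "control") for i in range(n_control)]
    rows += [(f"e2_{i + 1:03d}", "E2", "treated") for i in range(n_treated)]
    return pd.DataFrame(rows, columns=["line_id", "generation", "treatment"])


def simulate_traits(spec: TraitSpec, lines: pd.DataFrame) -> pd.DataFrame:
    """Simulate a long-format trait table for the given lines.

    ``lines`` needs columns ``line_id`` and ``treatment`` ("control" or
    "treated"); an optional ``n_samples`` column overrides
    ``spec.n_samples_per_line`` per line.  Each line draws one latent
    desaturation score and one between-line effect per trait; samples within
    a line add within-line noise.  Fatty-acid fractions are clipped at 0.
    """
    required = {"line_id", "treatment"}
    if not required <= set(lines.columns):
        missing = required - set(lines.columns)
        raise ValueError(f"lines metadata missing columns: {sorted(missing)}")
    bad = set(lines["treatment"]) - {"control", "treated"}
    if bad:
        raise ValueError(f"unknown treatment labels: {sorted(bad)}")

    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    for rec in lines.itertuples(index=False):
        grp = rec.treatment
        gen = getattr(rec, "generation", "")
        n_samples = int(getattr(rec, "n_samples", spec.n_samples_per_line))
        latent = rng.standard_normal()
        line_means: dict[str, float] = {}
        for trait, groups in spec.traits.items():
            params = groups[grp]
            sd_b = float(np.sqrt(params.between_line_var))
            loading = spec.latent_loadings.get(trait, 0.0) * (
                spec.latent_desaturation_effect
            )
            if loading != 0.0 and sd_b > 0:
                resid = float(np.sqrt(max(0.0, 1.0 - loading**2)))
                effect = sd_b * (loading * latent + resid * rng.standard_normal())
            else:
                effect = sd_b * rng.standard_normal()
            line_means[trait] = params.mean + effect
        for k in range(n_samples):
            sid = f"{rec.line_id}_n{k + 1:03d}"
            for trait, groups in spec.traits.items():
                params = groups[grp]
                sd_w = float(np.sqrt(params.within_line_var))
                value = line_means[trait] + sd_w * rng.standard_normal()
                if trait in FATTY_ACID_TRAITS:
                    value = max(0.0, value)
                rows.append(
                    (rec.line_id, gen, grp, sid, trait, value,
                     _TRAIT_UNITS.get(trait, ""))
                )
    return pd.DataFrame(
        rows,
        columns=["line_id", "generation", "treatment", "sample_id",
                 "trait", "value", "units"],
    )


def build_population_pedigree(
    n_e1: int,
    siliques_per_plant: int = 3,
    pooled_per_plant: int = 1,
    seeds_sown_per_selected_line: int = 10,
    n_selected_lines: int = 0,
) -> pd.DataFrame:
    """Build the accession ledger of the epimutagenised population.

    Each E1 plant contributes ``siliques_per_plant`` single-silique E2 seed
    accessions plus ``pooled_per_plant`` pooled-seed accessions (the
    sib-lines).  From the first ``n_selected_lines`` E1 plants,
    ``seeds_sown_per_selected_line`` seeds are sown to give E2 plants.

    Returns a ledger with columns ``accession_id, generation, parent,
    source_type``; ids are unique.
    """
    for name, v in (
        ("n_e1", n_e1),
        ("siliques_per_plant", siliques_per_plant),
        ("pooled_per_plant", pooled_per_plant),
        ("seeds_sown_per_selected_line", seeds_sown_per_selected_line),
        ("n_selected_lines", n_selected_lines),
    ):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if n_selected_lines > n_e1:
        raise ValueError("n_selected_lines cannot exceed n_e1")

    rows: list[tuple[str, str, str, str]] = []
    e1_ids = [f"E1_{i + 1:04d}" for i in range(n_e1)]
    for e1 in e1_ids:
        rows.append((e1, "E1", "E0_seed", "treated_seed"))
        for j in range(siliques_per_plant):
            rows.append((f"{e1}_sil{j + 1}", "E2", e1, "silique_seed"))
        for j in range(pooled_per_plant):
            rows.append((f"{e1}_pool{j + 1}", "E2", e1, "pooled_seed"))
    for e1 in e1_ids[:n_selected_lines]:
        for k in range(seeds_sown_per_selected_line):
            rows.append((f"{e1}_p{k + 1:02d}", "E2", e1, "sown_plant"))

    ledger = pd.DataFrame(
        rows, columns=["accession_id", "generation", "parent", "source_type"]
    )
    if ledger["accession_id"].duplicated().any():
        raise AssertionError("pedigree accession ids are not unique")
    return ledger


def pedigree_counts(ledger: pd.DataFrame) -> dict[str, int]:
    """Summary counts of a pedigree ledger (accessions vs plants)."""
    src = ledger["source_type"]
    return {
        "n_e1_plants": int((src == "treated_seed").sum()),
        "n_e2_seed_accessions": int(src.isin(["silique_seed", "pooled_seed"]).sum()),
        "n_e2_plants": int((src == "sown_plant").sum()),
    }
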