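"""AMOVA variance components, PhiPT, SSWP and the hypomethylation screen.

The analysis of molecular variance partitions pairwise squared Euclidean
distances between binary MSAP profiles into among- and within-group sums of
squares:

    SS_total  = sum_{i<j} d2_ij / N
    SS_within = sum_g sum_{i<j in g} d2_ij / n_g
    SS_among  = SS_total - SS_within

with df_among = G - 1 and df_within = N - G.  The within-group variance
component Vw is MS_within; the among-group component is
Va = (MS_among - Vw) / n0 with the average-group-size coefficient
n0 = (N - sum n_g^2 / N) / (G - 1).  PhiPT — the binary-marker analogue of
the Fst fixation index — is max(Va, 0) / (max(Va, 0) + Vw), and its
significance is assessed by permuting sample labels between groups (add-one
Monte-Carlo p-value, so 9,999 permutations floor at p = 0.0001).

The screen applies this to each line separately, comparing the line's
HpaII-digest samples against its MspI-digest samples: untreated lines show
strongly divergent enzyme profiles (methylation blocks HpaII), while
effectively demethylated lines converge (PhiPT near 0, non-significant p),
which is the line-classification rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msap_core import DistanceMatrix, MSAPMatrix, assert_paired

__all__ = [
    "AmovaResult",
    "LineScreenResult",
    "amova",
    "permutation_test",
    "sswp",
    "screen_lines",
    "screen_results_frame",
]


@dataclass
class AmovaResult:
    """Two-level AMOVA decomposition with PhiPT.

    ``p_value`` is None until a permutation test is attached.
    ``sswp_per_group`` maps group label -> within-group sum of squares.
    """

    ss_among: float
    ss_within: float
    ss_total: float
    df_among: int
    df_within: int
    ms_among: float
    ms_within: float
    va: float
    vw: float
    n0: float
    phi_pt: float
    sswp_per_group: dict
    p_value: float | None = None
    n_permutations: int | None = None


def _group_indices(ids, grouping) -> dict:
    grouping = pd.Series(grouping)
    missing = [s for s in ids if s not in grouping.index]
    if missing:
        raise ValueError(f"samples without group label: {missing[:5]}")
    labels = grouping.loc[list(ids)]
    groups: dict = {}
    for pos, lab in enumerate(labels):
        groups.setdefault(lab, []).append(pos)
    return {lab: np.asarray(idx, dtype=int) for lab, idx in groups.items()}


def _components_from_d2(D2: np.ndarray, groups: dict) -> dict:
    """Core AMOVA arithmetic on a squared-distance matrix.

    ``groups`` maps label -> integer positions.  Returns the full component
    dictionary; PhiPT clamps negative Va at zero.
    """
    N = D2.shape[0]
    G = len(groups)
    ss_total = float(np.triu(D2, k=1).sum()) / N
    ss_within = 0.0
    sswp = {}
    for lab, idx in groups.items():
        sub = D2[np.ix_(idx, idx)]
        s = float(np.triu(sub, k=1).sum()) / len(idx)
        sswp[lab] = s
        ss_within += s
    ss_among = ss_total - ss_within
    df_among = G - 1
    df_within = N - G
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    sizes = np.array([len(idx) for idx in groups.values()], dtype=float)
    n0 = (N - (sizes**2).sum() / N) / df_among
    vw = ms_within
    va = (ms_among - vw) / n0
    va_pos = max(va, 0.0)
    denom = va_pos + vw
    phi = va_pos / denom if denom > 0 else 0.0
    return dict(
        ss_among=ss_among, ss_within=ss_within, ss_total=ss_total,
        df_among=df_among, df_within=df_within,
        ms_among=ms_among, ms_within=ms_within,
        va=va, vw=vw, n0=n0, phi_pt=phi, sswp_per_group=sswp,
    )


def _validate_groups(groups: dict) -> None:
    if len(groups) < 2:
        raise ValueError("AMOVA needs at least 2 groups")
    for lab, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(
                f"group {lab!r} has {len(idx)} sample(s); each group needs >= 2"
            )


def amova(d: DistanceMatrix, grouping) -> AmovaResult:
    """Two-level AMOVA of a squared-Euclidean distance matrix.

    ``grouping`` maps sample id -> group label (mapping/Series).  Euclidean
    input is squared internally.
    """
    groups = _group_indices(d.ids, grouping)
    _validate_groups(groups)
    comp = _components_from_d2(d.squared(), groups)
    return AmovaResult(**comp)


def _phi_only(D2: np.ndarray, idx_lists: list[np.ndarray], N: int,
              n0: float, df_among: int, df_within: int,
              ss_total: float) -> float:
    """Fast PhiPT for permutation resampling (ss_total is label-invariant)."""
    ss_within = 0.0
    for idx in idx_lists:
        sub = D2[np.ix_(idx, idx)]
        ss_within += float(np.triu(sub, k=1).sum()) / len(idx)
    ms_among = (ss_total - ss_within) / df_among
    vw = ss_within / df_within
    va = max((ms_among - vw) / n0, 0.0)
    denom = va + vw
    return va / denom if denom > 0 else 0.0


def permutation_test(
    d: DistanceMatrix,
    grouping,
    n_permutations: int = 9999,
    rng_seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for PhiPT (labels shuffled, group sizes kept).

    p = (#{permuted PhiPT >= observed} + 1) / (n_permutations + 1); ties
    count against the hypothesis (conservative) and the add-one convention
    floors the p-value at 1/(n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    groups = _group_indices(d.ids, grouping)
    _validate_groups(groups)
    D2 = d.squared()
    comp = _components_from_d2(D2, groups)
    observed = comp["phi_pt"]
    N = D2.shape[0]
    sizes = [len(idx) for idx in groups.values()]
    bounds = np.cumsum([0] + sizes)
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(N)
        idx_lists = [perm[bounds[k]:bounds[k + 1]] for k in range(len(sizes))]
        phi = _phi_only(D2, idx_lists, N, comp["n0"], comp["df_among"],
                        comp["df_within"], comp["ss_total"])
        if phi >= observed - 1e-12:
            exceed += 1
    return (exceed + 1) / (n_permutations + 1)


def amova_with_permutation(
    d: DistanceMatrix, grouping, n_permutations: int = 9999,
    rng_seed: int | np.random.Generator = 0,
) -> AmovaResult:
    """AMOVA components plus the permutation p-value in one result."""
    result = amova(d, grouping)
    result.p_value = permutation_test(d, grouping, n_permutations, rng_seed)
    result.n_permutations = n_permutations
    return result


def sswp(d: DistanceMatrix, grouping, group) -> float:
    """Within-group sum of squares for one group: sum_{i<j in g} d2 / n_g."""
    groups = _group_indices(d.ids, grouping)
    if group not in groups:
        raise ValueError(f"group {group!r} not present")
    idx = groups[group]
    if len(idx) < 2:
        raise ValueError(f"group {group!r} needs >= 2 samples")
    sub = d.squared()[np.ix_(idx, idx)]
    return float(np.triu(sub, k=1).sum()) / len(idx)


@dataclass
class LineScreenResult:
    """Per-line isoschizomer-divergence screen outcome.

    ``classified_hypomethylated`` is True when the HpaII vs MspI divergence
    is non-significant (p_value > alpha): the two digests read the same
    underlying profile, i.e. the methylation that separates them is gone.
    """

    line_id: str
    phi_pt: float
    p_value: float
    classified_hypomethylated: bool
    sswp_hpaii: float
    sswp_mspi: float
    n_samples: int


def screen_lines(
    hpaii: MSAPMatrix,
    mspi: MSAPMatrix,
    alpha: float = 0.05,
    n_permutations: int = 9999,
    rng_seed: int = 0,
) -> list[LineScreenResult]:
    """Classify each line as effectively hypomethylated or not.

    For every line, the line's HpaII samples and its MspI samples form the
    two AMOVA groups; whole-sample labels are permuted between the enzyme
    groups.  Results are sorted by PhiPT ascending (most converged first).
    """
    assert_paired(hpaii, mspi)
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    results = []
    for line in dict.fromkeys(hpaii.line_ids):
        sample_ids = [s for s in hpaii.sample_ids if hpaii.line_ids[s] == line]
        if len(sample_ids) < 2:
            raise ValueError(f"line {line!r} has < 2 samples per enzyme")
        sub_h = hpaii.subset(sample_ids)
        sub_m = mspi.subset(sample_ids)
        stacked = pd.concat(
            [
                sub_h.values.set_axis([f"{s}|HpaII" for s in sample_ids]),
                sub_m.values.set_axis([f"{s}|MspI" for s in sample_ids]),
            ]
        )
        combined = MSAPMatrix(
            values=stacked,
            line_ids=pd.Series([line] * len(stacked), index=stacked.index),
            generations=pd.Series([""] * len(stacked), index=stacked.index),
            enzyme="paired",
        )
        d = pairwise_distance_squared(combined)
        grouping = pd.Series(
            ["HpaII"] * len(sample_ids) + ["MspI"] * len(sample_ids),
            index=stacked.index,
        )
        res = amova_with_permutation(d, grouping, n_permutations, rng)
        results.append(
            LineScreenResult(
                line_id=line,
                phi_pt=res.phi_pt,
                p_value=res.p_value,
                classified_hypomethylated=res.p_value > alpha,
                sswp_hpaii=res.sswp_per_group["HpaII"],
                sswp_mspi=res.sswp_per_group["MspI"],
                n_samples=len(sample_ids),
            )
        )
    results.sort(key=lambda r: r.phi_pt)
    return results


def pairwise_distance_squared(matrix: MSAPMatrix) -> DistanceMatrix:
    """Squared-Euclidean distance convenience wrapper (AMOVA convention)."""
    from .msap_core import pairwise_distance

    return pairwise_distance(matrix, metric="squared_euclidean")


def screen_results_frame(results: list[LineScreenResult]) -> pd.DataFrame:
    """Tabulate screen results (one row per line, PhiPT ascending)."""
    return pd.DataFrame(
        [
            {
                "line_id": r.line_id,
                "phi_pt": r.phi_pt,
                "p_value": r.p_value,
                "classified_hypomethylated": r.classified_hypomethylated,
                "sswp_hpaii": r.sswp_hpaii,
                "sswp_mspi": r.sswp_mspi,
                "n_samples": r.n_samples,
            }
            for r in results
        ]
    )
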