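"""Synthetic cohort generator with block-correlated three-domain structure.

Real score tables for this analysis are subject x item matrices with
bounded integer scores, strong within-domain correlation, weaker
between-domain correlation, and a handful of bridge associations.  The
generator emulates exactly that via a Gaussian copula: a target
correlation matrix is assembled block-wise, repaired to the nearest
positive-semidefinite correlation matrix (eigenvalue clipping followed by
re-standardization), latent multivariate normals are drawn, and each
column is mapped through its item's mean/SD, rounded to integers and
clamped to the instrument's score range.

Rounding and clamping mildly attenuate correlations at extreme means;
this is a property of bounded integer scales, and is left uncorrected.
Sign conventions are taken as given on the latent scale: the generator
never flips correlations to match item orientations.

Two illustrative presets mimic the qualitative structure of unipolar
(MDD-like) and bipolar (BD-like) depression cohorts: the MDD-like arm has
strong affective-psychosocial bridges and no direct affective-
neurocognitive edges; the BD-like arm has a hyperconnected psychosocial
block with neurocognitive bridges through global cognition (MCA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .battery import Battery, Domain, ScoreTable, default_battery
from .errors import ConfigError

_DOMAINS = tuple(d.value for d in Domain)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class BlockSpec:
    """Block-wise latent correlation targets.

    ``within`` maps each domain to its within-block correlation;
    ``between`` maps unordered domain pairs to the between-block value;
    ``bridge_edges`` lists item-pair overrides applied last, for planted
    bridges between specific nodes.
    """

    within: dict[str, float] = field(default_factory=dict)
    between: dict[tuple[str, str], float] = field(default_factory=dict)
    bridge_edges: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        for d, r in self.within.items():
            if d not in _DOMAINS:
                raise ConfigError(f"unknown domain {d!r}")
            _check_rho(r, f"within[{d}]")
        for pair, r in self.between.items():
            for d in pair:
                if d not in _DOMAINS:
                    raise ConfigError(f"unknown domain {d!r}")
            _check_rho(r, f"between[{pair}]")
        for a, b, r in self.bridge_edges:
            _check_rho(r, f"bridge ({a}, {b})")


def _check_rho(r: float, what: str) -> None:
    if not -1.0 < r < 1.0:
        raise ConfigError(f"{what}: correlation must be in (-1, 1), got {r}")


@dataclass(frozen=True)
class CohortConfig:
    """One cohort draw: battery, size, latent structure, margins, seed."""

    battery: Battery
    n_subjects: int
    block_spec: BlockSpec
    item_means: dict[str, float]
    item_sds: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        for lab in self.battery.labels:
            if lab not in self.item_means:
                raise ConfigError(f"missing mean for item {lab!r}")
            if lab not in self.item_sds:
                raise ConfigError(f"missing sd for item {lab!r}")
            it = self.battery[lab]
            m = self.item_means[lab]
            if not it.score_min <= m <= it.score_max:
                raise ConfigError(
                    f"mean {m} for {lab!r} outside score range "
                    f"[{it.score_min}, {it.score_max}]"
                )
            if self.item_sds[lab] <= 0:
                raise ConfigError(f"sd for {lab!r} must be positive")


@dataclass(frozen=True)
class PairedDesign:
    """Baseline (T0) plus follow-up (T1) derived from retained subjects.

    T1 latent off-diagonal correlations equal ``correlation_attenuation``
    times the T0 targets (global connectivity loss), and
    ``treatment_shift`` adds per-item mean changes at T1.
    """

    t0: CohortConfig
    t1: CohortConfig
    subject_retention: float = 1.0
    treatment_shift: dict[str, float] = field(default_factory=dict)
    correlation_attenuation: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.subject_retention <= 1.0:
            raise ConfigError("subject_retention must be in (0, 1]")
        if not 0.0 <= self.correlation_attenuation <= 1.0:
            raise ConfigError("correlation_attenuation must be in [0, 1]")
        for lab in self.treatment_shift:
            if lab not in self.t0.battery.labels:
                raise ConfigError(f"treatment_shift for unknown item {lab!r}")


def _nearest_psd_correlation(R: np.ndarray, tol: float = 1e-12,
                             max_iter: int = 100) -> np.ndarray:
    """Project to the nearest PSD correlation matrix.

    Eigenvalue clipping at zero followed by re-standardization to unit
    diagonal, iterated because re-standardization can reintroduce tiny
    negative eigenvalues.
    """
    A = (R + R.T) / 2.0
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(A)
        if vals.min() >= -tol:
            break
        vals = np.clip(vals, 0.0, None)
        A = (vecs * vals) @ vecs.T
        d = np.sqrt(np.clip(np.diag(A), 1e-12, None))
        A = A / np.outer(d, d)
        A = (A + A.T) / 2.0
        np.fill_diagonal(A, 1.0)
    return A


def build_target_correlation(spec: BlockSpec, battery: Battery) -> np.ndarray:
    """Assemble the block-wise target and repair it to a PSD correlation.

    Within-domain entries first, then between-domain entries, then
    bridge-edge overrides; finally the nearest-PSD projection.
    """
    labels = battery.labels
    doms = [it.domain.value for it in battery.items]
    k = len(labels)
    R = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if doms[i] == doms[j]:
                r = spec.within.get(doms[i], 0.0)
            else:
                key = _pair_key(doms[i], doms[j])
                r = spec.between.get(tuple(key), 0.0)
                if r == 0.0:
                    r = spec.between.get((key[1], key[0]), 0.0)
            R[i, j] = R[j, i] = r
    for a, b, r in spec.bridge_edges:
        if a not in labels or b not in labels:
            missing = a if a not in labels else b
            raise ConfigError(f"bridge edge references unknown item {missing!r}")
        i, j = labels.index(a), labels.index(b)
        R[i, j] = R[j, i] = r
    return _nearest_psd_correlation(R)


def _latent_factor(R: np.ndarray) -> np.ndarray:
    """Matrix square root of a PSD correlation (eigh-based, singular-safe)."""
    vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def _draw(config: CohortConfig, R: np.ndarray, rng: np.random.Generator,
          subject_ids: list[str]) -> ScoreTable:
    n, k = len(subject_ids), len(config.battery)
    L = _latent_factor(R)
    Z = rng.standard_normal((n, k)) @ L.T
    X = np.empty_like(Z)
    for j, it in enumerate(config.battery.items):
        col = config.item_means[it.label] + config.item_sds[it.label] * Z[:, j]
        col = np.rint(col)
        X[:, j] = np.clip(col, it.score_min, it.score_max)
    return ScoreTable(battery=config.battery, subject_ids=subject_ids, values=X)


def sample_cohort(config: CohortConfig) -> ScoreTable:
    """Draw one cohort: Gaussian copula with integer rounding and clamping.

    Fully reproducible: the output is a pure function of the config
    (including its seed).
    """
    R = build_target_correlation(config.block_spec, config.battery)
    rng = np.random.default_rng(config.seed)
    ids = [f"S{i:04d}" for i in range(config.n_subjects)]
    return _draw(config, R, rng, ids)


def sample_paired(design: PairedDesign) -> tuple[ScoreTable, ScoreTable]:
    """Draw a T0 cohort and its retained-subject T1 follow-up.

    T1 subjects are a seeded random subset of the T0 subjects of size
    round(retention * n_t0); T1 latent correlations are the attenuated T0
    targets, and treatment shifts move T1 means.
    """
    n0 = design.t0.n_subjects
    n1 = int(round(design.subject_retention * n0))
    if n1 < 2:
        raise ConfigError(
            f"retention {design.subject_retention} of {n0} subjects leaves "
            f"{n1} at T1 (need >= 2)"
        )
    t0_table = sample_cohort(design.t0)

    R0 = build_target_correlation(design.t0.block_spec, design.t0.battery)
    R1 = design.correlation_attenuation * R0
    np.fill_diagonal(R1, 1.0)
    R1 = _nearest_psd_correlation(R1)

    shifted_means = dict(design.t1.item_means)
    for lab, delta in design.treatment_shift.items():
        it = design.t1.battery[lab]
        shifted_means[lab] = float(
            np.clip(shifted_means[lab] + delta, it.score_min, it.score_max)
        )
    t1_config = replace(design.t1, item_means=shifted_means)

    rng = np.random.default_rng(design.t1.seed)
    keep = np.sort(rng.choice(n0, size=n1, replace=False))
    ids = [t0_table.subject_ids[i] for i in keep]
    t1_table = _draw(t1_config, R1, rng, ids)
    return t0_table, t1_table


# --------------------------------------------------------------------------
# Illustrative presets (fixtures mimicking the qualitative cohort structure,
# not parameter estimates).  Cross-domain correlations with the
# neurocognitive block are negative because those items are scored
# higher-is-better while the affective and psychosocial items are scored
# higher-is-worse.

_T0_MEANS = {
    "MCA": 22.0, "MMS": 24.0, "FAB": 13.0, "FAS": 30.0, "Vcb": 34.0,
    "REY": 35.0, "RDC": 7.0, "SPAN_A": 5.5, "SPAN_I": 4.0,
    "BDI": 28.0, "HDR": 22.0,
    "Cgn": 9.0, "Occ": 10.0, "Atn": 7.0, "Lsr": 4.0, "Int": 11.0, "Fnn": 4.0,
}
_T0_SDS = {
    "MCA": 4.0, "MMS": 3.5, "FAB": 3.0, "FAS": 9.0, "Vcb": 8.0,
    "REY": 10.0, "RDC": 3.0, "SPAN_A": 1.2, "SPAN_I": 1.2,
    "BDI": 9.0, "HDR": 6.0,
    "Cgn": 3.0, "Occ": 3.5, "Atn": 3.0, "Lsr": 1.5, "Int": 4.0, "Fnn": 1.5,
}
# T1: depression scales improve, FAST burdens decrease, cognition edges up
_T1_SHIFT = {
    "BDI": -10.0, "HDR": -8.0,
    "Cgn": -2.0, "Occ": -2.0, "Atn": -1.5, "Lsr": -1.0, "Int": -2.5, "Fnn": -1.0,
    "MCA": 1.5, "MMS": 1.0, "FAB": 1.0, "FAS": 3.0,
}

MDD_LIKE_BLOCKS = BlockSpec(
    within={"neurocognitive": 0.50, "affective": 0.65, "psychosocial": 0.50},
    between={
        ("affective", "psychosocial"): 0.40,
        ("affective", "neurocognitive"): 0.0,
        ("neurocognitive", "psychosocial"): -0.20,
    },
    bridge_edges=(("MCA", "Cgn", -0.40), ("MMS", "Cgn", -0.35)),
)

BD_LIKE_BLOCKS = BlockSpec(
    within={"neurocognitive": 0.35, "affective": 0.60, "psychosocial": 0.65},
    between={
        ("affective", "psychosocial"): 0.35,
        ("affective", "neurocognitive"): -0.20,
        ("neurocognitive", "psychosocial"): -0.15,
    },
    bridge_edges=(("MCA", "Cgn", -0.45), ("MCA", "BDI", -0.35),
                  ("Int", "Occ", 0.70)),
)


def preset_design(
    kind: str,
    seed: int,
    n_t0: int | None = None,
    n_t1: int | None = None,
    correlation_attenuation: float = 0.4,
) -> PairedDesign:
    """Paired MDD-like or BD-like design at the study's cohort sizes.

    Defaults: 87 MDD-like subjects at baseline with 16 retained, 56
    BD-like with 29 retained, and an attenuation of 0.4 emulating the
    observed T0-to-T1 loss of connectivity.
    """
    kind = kind.lower()
    if kind == "mdd":
        blocks, default_n0, default_n1 = MDD_LIKE_BLOCKS, 87, 16
    elif kind == "bd":
        blocks, default_n0, default_n1 = BD_LIKE_BLOCKS, 56, 29
    else:
        raise ConfigError(f"unknown preset {kind!r} (expected 'mdd' or 'bd')")
    n_t0 = default_n0 if n_t0 is None else n_t0
    n_t1 = default_n1 if n_t1 is None else n_t1
    battery = default_battery()
    t0 = CohortConfig(battery=battery, n_subjects=n_t0, block_spec=blocks,
                      item_means=dict(_T0_MEANS), item_sds=dict(_T0_SDS),
                      seed=seed)
    t1 = CohortConfig(battery=battery, n_subjects=n_t1, block_spec=blocks,
                      item_means=dict(_T0_MEANS), item_sds=dict(_T0_SDS),
                      seed=seed + 1)
    return PairedDesign(
        t0=t0, t1=t1,
        subject_retention=n_t1 / n_t0,
        treatment_shift=dict(_T1_SHIFT),
        correlation_attenuation=correlation_attenuation,
    )
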