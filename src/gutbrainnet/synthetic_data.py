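"""Synthetic cohort generator.

Emulates the study conditions of a gut-metabolite / brain-connectivity
cohort: 63 subjects (29 male / 34 female), ages 18-60, BMI ~ N(25.82,
4.93), Yale Food Addiction Scale scores ~ N(1.24, 1.25) observed for 42
of 63 subjects, HAD anxiety ~ N(4.25, 3.41), three positively skewed
(log-normal) fecal tryptophan metabolites (indole, skatole,
indoleacetic acid), per-subject region time series (243 samples by
default, one resting-state scan at TR = 2 s), and per-subject
fiber-count matrices with fixed region volumes.

Cross-block dependence is induced by a single latent factor ``L`` per
subject: every variable ``v`` with loading ``rho_v`` is generated as

    v = mu_v + sigma_v * (rho_v * L + sqrt(1 - rho_v^2) * eps)

before being mapped onto its marginal scale (exponentiation for
metabolites, rounding/truncation for questionnaire scores).  A planted
pair (a, b, rho) therefore has population Pearson correlation
``rho_a * rho_b = rho`` on the latent scale.  The same ``L`` can shift
designated time-series correlations (additively, ``beta * L``) and
fiber-count intensities (multiplicatively, ``exp(gamma * L)``).
"""

from __future__ import annotations

import dataclasses
import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import make_parcellation, roi_labels

logger = logging.getLogger(__name__)

METABOLITES = ("indole", "skatole", "iaa")
CLINICAL = ("bmi", "yfas", "had_anxiety")


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive an independent, stable per-stage random generator."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


@dataclass
class CohortSpec:
    """Study-condition parameters for one synthetic cohort.

    Marginal defaults are the cohort characteristics listed in the
    module docstring; ``effect_map`` entries are (variable_a,
    variable_b, target correlation) triples planted through the shared
    latent factor.  Variables named like ``func:S_R_NAcc`` or
    ``anat:B_L_Amg`` address the directly generated brain-metric block
    (see :func:`generate_metric_block`).
    """

    n_subjects: int = 63
    seed: int = 0
    n_regions: int = 165
    t_points: int = 243
    n_male: int | None = None          # default: round(n * 29/63)
    yfas_completion: int | None = None  # default: round(n * 42/63)
    dti_excluded: int = 1              # anatomical scans dropped (last ids)

    age_mean: float = 29.42
    age_sd: float = 10.76
    age_range: tuple[float, float] = (18.0, 60.0)
    bmi_mean: float = 25.82
    bmi_sd: float = 4.93
    yfas_mean: float = 1.24
    yfas_sd: float = 1.25
    anx_mean: float = 4.25
    anx_sd: float = 3.41

    # log-scale metabolite marginals (arbitrary units, log-normal)
    metabolite_log_mean: dict = field(default_factory=lambda: {
        "indole": 4.0, "skatole": 2.0, "iaa": 3.0})
    metabolite_log_sd: dict = field(default_factory=lambda: {
        "indole": 0.8, "skatole": 0.9, "iaa": 0.7})

    effect_map: tuple = ()
    # direct per-variable loadings on the latent factor; overrides any
    # loading resolved from effect_map for the same variable
    latent_loadings: dict = field(default_factory=dict)

    # time-series baseline: round-robin communities, block-constant r.
    # Values sit near the retention threshold tanh(0.3) so that edge
    # sets (and hence path structure) vary across subjects.
    n_communities: int = 4
    within_r: float = 0.35
    between_r: float = 0.20
    ts_planted_edges: tuple = ()       # (label_a, label_b, beta)

    # fiber counts: Poisson-lognormal intensities by community
    # membership; the dispersion term makes shortest-path structure
    # subject-specific, as tractography counts are overdispersed.
    fiber_within: float = 120.0
    fiber_between: float = 25.0
    fiber_dispersion: float = 0.5
    fiber_planted_edges: tuple = ()    # (label_a, label_b, gamma)

    def __post_init__(self) -> None:
        if self.n_male is None:
            self.n_male = int(round(self.n_subjects * 29 / 63))
        if self.yfas_completion is None:
            self.yfas_completion = int(round(self.n_subjects * 42 / 63))
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValueError(
                f"n_subjects must be >= 4, got {self.n_subjects}")
        if not (0 < self.yfas_completion <= self.n_subjects):
            raise ValueError(
                f"yfas_completion must be in (0, n_subjects], got "
                f"{self.yfas_completion}")
        if not (0 <= self.n_male <= self.n_subjects):
            raise ValueError("n_male out of range")
        if self.t_points < 8:
            raise ValueError(f"t_points must be >= 8, got {self.t_points}")
        if not (0 <= self.dti_excluded < self.n_subjects):
            raise ValueError("dti_excluded out of range")
        for sd_name in ("age_sd", "bmi_sd", "yfas_sd", "anx_sd"):
            if getattr(self, sd_name) <= 0:
                raise ValueError(f"{sd_name} must be positive")
        for name, sd in self.metabolite_log_sd.items():
            if sd <= 0:
                raise ValueError(f"log-SD for {name} must be positive")
        if self.fiber_within < 0 or self.fiber_between < 0:
            raise ValueError("fiber-count intensities must be nonnegative")
        if self.fiber_dispersion < 0:
            raise ValueError("fiber_dispersion must be nonnegative")
        for a, b, rho in self.effect_map:
            if not abs(rho) < 1:
                raise ValueError(
                    f"planted correlation for ({a}, {b}) must satisfy "
                    f"|rho| < 1, got {rho}")
        for v, rho in self.latent_loadings.items():
            if not abs(rho) < 1:
                raise ValueError(
                    f"latent loading for {v} must satisfy |rho| < 1, "
                    f"got {rho}")
        for _, _, beta in self.ts_planted_edges:
            if not np.isfinite(beta):
                raise ValueError("time-series shift beta must be finite")

    # -- latent-factor loadings --------------------------------------
    def loadings(self) -> dict[str, float]:
        """Resolve per-variable latent loadings from ``effect_map``.

        Each pair (a, b, rho) requires loading_a * loading_b = rho.
        A variable seen for the first time in a pair receives
        sqrt(|rho|) (the sign goes to the second variable); a variable
        already constrained keeps its loading and the partner absorbs
        the ratio.
        """
        load: dict[str, float] = {}
        for a, b, rho in self.effect_map:
            if a in load and b in load:
                got = load[a] * load[b]
                if not math.isclose(got, rho, abs_tol=1e-9):
                    raise ValueError(
                        f"effect_map over-constrains ({a}, {b}): implied "
                        f"correlation {got:.4f} != requested {rho:.4f}")
            elif a in load:
                load[b] = rho / load[a]
            elif b in load:
                load[a] = rho / load[b]
            else:
                r = math.sqrt(abs(rho))
                load[a] = r
                load[b] = math.copysign(r, rho) if rho != 0 else 0.0
            for v in (a, b):
                if abs(load[v]) >= 1:
                    raise ValueError(
                        f"resolved loading for {v} is {load[v]:.4f}; "
                        f"|loading| must be < 1")
        load.update(self.latent_loadings)
        return load

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)

    def regions(self):
        return make_parcellation(self.n_regions, seed=self.seed)


def _latent_mix(rho: float, latent: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal(latent.shape[0])
    return rho * latent + math.sqrt(1.0 - rho * rho) * eps


def generate_subjects(spec: CohortSpec) -> pd.DataFrame:
    """Draw the subject table (demographics, scores, metabolites).

    Deterministic given ``spec`` (including its seed).  The hidden
    latent factor is emitted in column ``latent`` for test
    introspection.  YFAS is missing (NaN) for exactly
    ``n_subjects - yfas_completion`` subjects — deterministically the
    last ids, so pairwise-complete sample sizes are reproducible.
    """
    spec.validate()
    n = spec.n_subjects
    rng = child_rng(spec.seed, "subjects")
    load = spec.loadings()
    latent = rng.standard_normal(n)

    age = np.clip(spec.age_mean + spec.age_sd *
                  _latent_mix(load.get("age", 0.0), latent, rng),
                  *spec.age_range)
    sex = np.zeros(n, dtype=int)
    sex[:spec.n_male] = 1                       # 1 = male, 0 = female
    rng.shuffle(sex)

    bmi = np.clip(spec.bmi_mean + spec.bmi_sd *
                  _latent_mix(load.get("bmi", 0.0), latent, rng), 10.0, 60.0)
    yfas = np.clip(np.round(spec.yfas_mean + spec.yfas_sd *
                            _latent_mix(load.get("yfas", 0.0), latent, rng)),
                   0, 7).astype(float)
    yfas[spec.yfas_completion:] = np.nan
    anx = np.clip(np.round(spec.anx_mean + spec.anx_sd *
                           _latent_mix(load.get("had_anxiety", 0.0),
                                       latent, rng)),
                  0, 21).astype(float)

    cols = {
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "age": age, "sex": sex, "bmi": bmi, "yfas": yfas,
        "had_anxiety": anx,
    }
    for m in METABOLITES:
        z = _latent_mix(load.get(m, 0.0), latent, rng)
        cols[m] = np.exp(spec.metabolite_log_mean[m] +
                         spec.metabolite_log_sd[m] * z)
    cols["latent"] = latent
    return pd.DataFrame(cols)


# -- positive-semidefinite repair -------------------------------------

def nearest_correlation(C: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Repair a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the result is
    re-normalized to a unit diagonal.
    """
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    if w.min() >= eig_floor:
        out = C.copy()
    else:
        out = (V * np.clip(w, eig_floor, None)) @ V.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _baseline_correlation(spec: CohortSpec) -> np.ndarray:
    comm = np.arange(spec.n_regions) % spec.n_communities
    C = np.where(comm[:, None] == comm[None, :],
                 spec.within_r, spec.between_r).astype(float)
    np.fill_diagonal(C, 1.0)
    return C


def _label_index(regions: pd.DataFrame) -> dict[str, int]:
    return {lab: i for i, lab in enumerate(regions["label"])}


def generate_timeseries(subjects: pd.DataFrame, regions: pd.DataFrame,
                        spec: CohortSpec) -> dict[str, np.ndarray]:
    """Per-subject region time series (t_points x n_regions).

    Each subject's series is drawn from a zero-mean multivariate normal
    whose correlation matrix is the block baseline, with each planted
    ROI pair shifted by ``beta * L`` (clipped into (-0.99, 0.99)) and
    repaired to the nearest positive semi-definite correlation matrix.
    """
    spec.validate()
    n_regions = len(regions)
    if spec.t_points <= n_regions:
        logger.warning(
            "t_points (%d) <= n_regions (%d): sample correlation "
            "matrices will be rank deficient", spec.t_points, n_regions)
    rng = child_rng(spec.seed, "timeseries")
    idx = _label_index(regions)
    planted = [(idx[a], idx[b], beta) for a, b, beta in spec.ts_planted_edges]
    for a, b, _ in spec.ts_planted_edges:
        if a not in idx or b not in idx:  # pragma: no cover - idx above raises
            raise KeyError(a if a not in idx else b)

    C0 = _baseline_correlation(spec)
    base_factor = None
    out: dict[str, np.ndarray] = {}
    for sid, L in zip(subjects["subject_id"], subjects["latent"]):
        if planted:
            C = C0.copy()
            for i, j, beta in planted:
                C[i, j] = C[j, i] = float(
                    np.clip(C0[i, j] + beta * L, -0.99, 0.99))
            C = nearest_correlation(C)
            w, V = np.linalg.eigh(C)
            factor = V * np.sqrt(np.clip(w, 0.0, None))
        else:
            if base_factor is None:
                C = nearest_correlation(C0)
                w, V = np.linalg.eigh(C)
                base_factor = V * np.sqrt(np.clip(w, 0.0, None))
            factor = base_factor
        Z = rng.standard_normal((spec.t_points, n_regions))
        out[sid] = Z @ factor.T
    return out


def generate_fiber_counts(subjects: pd.DataFrame, regions: pd.DataFrame,
                          spec: CohortSpec
                          ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-subject symmetric fiber-count matrices plus region volumes.

    Counts for each unordered region pair are independent Poisson draws
    with community-structured intensity; planted edges multiply the
    intensity by ``exp(gamma * L)``.  The diagonal is zero; volumes are
    taken from the region table (subject-invariant).
    """
    spec.validate()
    if spec.fiber_within < 0 or spec.fiber_between < 0:
        raise ValueError("fiber-count intensities must be nonnegative")
    n = len(regions)
    rng = child_rng(spec.seed, "fibers")
    idx = _label_index(regions)
    comm = np.arange(n) % spec.n_communities
    lam0 = np.where(comm[:, None] == comm[None, :],
                    spec.fiber_within, spec.fiber_between).astype(float)
    np.fill_diagonal(lam0, 0.0)
    planted = [(idx[a], idx[b], g) for a, b, g in spec.fiber_planted_edges]
    iu = np.triu_indices(n, k=1)

    out: dict[str, np.ndarray] = {}
    for sid, L in zip(subjects["subject_id"], subjects["latent"]):
        lam = lam0
        if planted:
            lam = lam0.copy()
            for i, j, g in planted:
                lam[i, j] = lam[j, i] = lam0[i, j] * math.exp(g * L)
        lam_pair = lam[iu]
        if spec.fiber_dispersion > 0:
            lam_pair = lam_pair * np.exp(
                spec.fiber_dispersion * rng.standard_normal(lam_pair.shape)
                - 0.5 * spec.fiber_dispersion ** 2)
        counts = np.zeros((n, n), dtype=np.int64)
        counts[iu] = rng.poisson(lam_pair)
        counts = counts + counts.T
        out[sid] = counts
    return out, regions["volume"].to_numpy(dtype=float)


def generate_metric_block(subjects: pd.DataFrame, spec: CohortSpec,
                          variables: list[str] | None = None) -> pd.DataFrame:
    """Directly generated brain-metric block for calibration studies.

    Bypasses the imaging simulation: each brain-metric variable (named
    like ``func:S_R_NAcc``) is drawn on the latent scale with its
    ``effect_map`` loading, giving exact control over the population
    correlation between a metabolite and a metric — which the
    time-series route cannot calibrate.  Values are z-scores (rank
    analyses are scale-free).
    """
    if variables is None:
        variables = default_metric_variables()
    load = spec.loadings()
    rng = child_rng(spec.seed, "metric_block")
    latent = subjects["latent"].to_numpy()
    data = {v: _latent_mix(load.get(v, 0.0), latent, rng)
            for v in variables}
    block = pd.DataFrame(data)
    block.insert(0, "subject_id", subjects["subject_id"].to_numpy())
    if spec.dti_excluded:
        anat_cols = [v for v in variables if v.startswith("anat:")]
        block.loc[block.index[-spec.dti_excluded:], anat_cols] = np.nan
    return block


def default_metric_variables() -> list[str]:
    """The 48 brain-metric variable names: 12 ROIs x {S, B} x modality."""
    return [f"{mod}:{metric}_{lab}"
            for mod in ("func", "anat")
            for metric in ("S", "B")
            for lab in roi_labels()]
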