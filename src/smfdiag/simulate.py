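"""Synthetic LDI-MS serum-fingerprint cohorts with known ground truth.

Real nanoparticle-assisted LDI-MS serum profiles are not publicly deposited for
this kind of study, so every downstream stage of the pipeline is exercised on
simulated cohorts that emulate the regime of such data: ~120,000-point profile
spectra over m/z 100-1000, on the order of 900 detectable peak species, a small
number of case/control-informative species with modest fold changes, Na+/K+
adduct pairs sharing analyte abundance, a smooth decaying chemical baseline and
non-negative detector noise.

The generative model per sample is

    I(m) = g_s * sum_i A_{s,i} * N(m; mu_i, sigma) + B(m) + eps(m)

with g_s a global log-normal sample scale, A_{s,i} log-normal peak areas
jittered per sample around catalog base areas (case samples multiply the
informative species by their fold change), B an exponential-decay baseline and
eps truncated-Gaussian noise. Because the only case/control difference is a
mean shift in the log-areas of the informative species, the Bayes-optimal AUC
of the cohort has the closed two-Gaussian form Phi(Delta / sqrt(2)) with
Delta^2 = sum_i (log fc_i / tau)^2, tau the per-peak log jitter; see
:func:`bayes_auc`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "K_NA_MASS_DIFF",
    "SimConfig",
    "PeakCatalog",
    "build_catalog",
    "generate_spectrum",
    "generate_cohort",
    "iter_cohort",
    "bayes_auc",
    "jitter_for_bayes_auc",
]

# K+ minus Na+ adduct mass gap (monoisotopic), Da
K_NA_MASS_DIFF = 38.9637065 - 22.9897693


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation settings.

    Parameters
    ----------
    n_case, n_control
        Group sizes. The discovery-scale default elsewhere in the project is
        357/374.
    n_species
        Number of distinct peak species in the serum fingerprint (default 908).
    n_informative
        Species whose abundance differs between groups (default 4).
    axis_points, mz_range
        Profile m/z axis: number of grid points and (low, high) in Da.
    peak_sigma
        Gaussian peak width (sd) in Da. The default gives FWHM of about three
        axis steps at 120,000 points over 900 Da.
    min_spacing
        Minimum gap between catalog m/z centers in Da. Must be >= 4*peak_sigma;
        the default 0.5 Da keeps neighbouring species well clear of the
        downstream alignment tolerance.
    base_log_mean, base_log_sd
        Log-normal distribution of species base peak areas.
    baseline_amplitude, baseline_decay
        Exponential chemical baseline B(m) = amplitude * exp(-(m - lo)/decay).
    noise_sd
        Truncated-Gaussian (>= 0) additive noise scale, intensity units.
    sample_cv
        Coefficient of variation of the global per-sample intensity scale.
    peak_jitter_sd
        Per-sample, per-peak log-normal jitter sd of peak areas; the dominant
        biological/technical noise knob and the tau of :func:`bayes_auc`.
    adduct_fraction
        Fraction of species given a K+ adduct partner sharing analyte
        abundance (correlation adduct_rho in log-area).
    fold_change_range
        Uniform range informative fold changes are drawn from.
    seed
        Master seed; all catalog and cohort randomness derives from it.
    """

    n_case: int = 357
    n_control: int = 374
    n_species: int = 908
    n_informative: int = 4
    axis_points: int = 120_000
    mz_range: tuple[float, float] = (100.0, 1000.0)
    peak_sigma: Optional[float] = None
    min_spacing: Optional[float] = None
    base_log_mean: float = 4.605170185988092  # log(100)
    base_log_sd: float = 1.0
    baseline_amplitude: float = 500.0
    baseline_decay: float = 150.0
    noise_sd: float = 20.0
    sample_cv: float = 0.15
    peak_jitter_sd: float = 0.30
    adduct_fraction: float = 0.3
    adduct_rho: float = 0.8
    fold_change_range: tuple[float, float] = (1.09, 2.30)
    seed: int = 0
    catalog_seed: Optional[int] = None  # defaults to seed: same catalog, new noise

    def __post_init__(self) -> None:
        if self.n_case < 0 or self.n_control < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_species <= 0 or self.axis_points <= 1:
            raise ValueError("n_species and axis_points must be positive")
        if not 0 <= self.n_informative <= self.n_species:
            raise ValueError("n_informative must lie in [0, n_species]")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValueError("mz_range must be (low, high) with low < high")
        flo, fhi = self.fold_change_range
        if not 0 <= flo <= fhi:
            raise ValueError("fold_change_range must satisfy 0 <= low <= high")
        step = (hi - lo) / (self.axis_points - 1)
        if self.peak_sigma is None:
            # FWHM of about three axis steps (0.0096 Da at the 120k default)
            object.__setattr__(self, "peak_sigma", float(3 * step / 2.3548))
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be positive")
        if self.min_spacing is None:
            object.__setattr__(self, "min_spacing", float(max(0.5, 4 * self.peak_sigma)))
        if self.min_spacing < 4 * self.peak_sigma:
            raise ValueError(
                "min_spacing must be at least 4*peak_sigma to keep species resolvable"
            )

    @property
    def mz_axis(self) -> np.ndarray:
        lo, hi = self.mz_range
        return np.linspace(lo, hi, self.axis_points)


@dataclass
class PeakCatalog:
    """Ground-truth species table for one simulated cohort.

    ``base_intensity`` is the Gaussian peak *area* of the species at the
    log-normal median; peak height on the axis is area / (sigma * sqrt(2*pi)).
    ``adduct_partner`` is -1 for unpaired species. ``fold_change`` is exactly
    1.0 for every non-informative species.
    """

    mz_center: np.ndarray
    base_log_intensity: np.ndarray
    adduct_partner: np.ndarray
    informative: np.ndarray
    fold_change: np.ndarray
    config: SimConfig

    def __len__(self) -> int:
        return len(self.mz_center)

    @property
    def base_intensity(self) -> np.ndarray:
        return np.exp(self.base_log_intensity)

    @property
    def informative_idx(self) -> np.ndarray:
        return np.flatnonzero(self.informative)

    def to_json(self) -> str:
        d = {
            "mz_center": self.mz_center.tolist(),
            "base_log_intensity": self.base_log_intensity.tolist(),
            "adduct_partner": self.adduct_partner.tolist(),
            "informative": self.informative.astype(int).tolist(),
            "fold_change": self.fold_change.tolist(),
            "config": asdict(self.config),
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "PeakCatalog":
        d = json.loads(s)
        cfg = d["config"]
        cfg["mz_range"] = tuple(cfg["mz_range"])
        cfg["fold_change_range"] = tuple(cfg["fold_change_range"])
        return cls(
            mz_center=np.asarray(d["mz_center"], dtype=float),
            base_log_intensity=np.asarray(d["base_log_intensity"], dtype=float),
            adduct_partner=np.asarray(d["adduct_partner"], dtype=int),
            informative=np.asarray(d["informative"], dtype=bool),
            fold_change=np.asarray(d["fold_change"], dtype=float),
            config=SimConfig(**cfg),
        )


def _sample_spaced_positions(
    rng: np.random.Generator, n: int, lo: float, hi: float, spacing: float
) -> np.ndarray:
    """Uniformly sample n sorted positions in [lo, hi] with pairwise gap >= spacing.

    Uses the measure-preserving shift trick: draw n ordered uniforms on the
    shrunk interval and add back i*spacing.
    """
    slack = (hi - lo) - (n - 1) * spacing
    if slack <= 0:
        raise ValueError(
            f"cannot place {n} species with minimum spacing {spacing:g} Da "
            f"inside {hi - lo:g} Da: need {(n - 1) * spacing:g} Da"
        )
    u = np.sort(rng.uniform(0.0, slack, size=n))
    return lo + u + spacing * np.arange(n)


def build_catalog(config: SimConfig) -> PeakCatalog:
    """Draw a seeded species catalog: centers, base areas, adduct pairs, markers.

    Centers are kept 5 peak-sigma inside the axis range and at least
    ``min_spacing`` apart. A fraction of species is re-positioned as K+ adduct
    partners exactly ``K_NA_MASS_DIFF`` above their Na+ counterpart.
    Informative species are drawn from the adduct-unpaired pool so that the
    closed-form Bayes AUC of the cohort stays exact (a correlated adduct
    partner would otherwise act as a noise-cancelling covariate).
    """
    cat_seed = config.seed if config.catalog_seed is None else config.catalog_seed
    rng = np.random.default_rng(np.random.SeedSequence([cat_seed, 0x5EED]))
    lo, hi = config.mz_range
    margin = 5 * config.peak_sigma
    n = config.n_species

    n_pairs = int(round(config.adduct_fraction * n / 2))
    n_anchor = n - n_pairs  # species placed freely; pairs hang off anchors
    centers = _sample_spaced_positions(
        rng, n_anchor, lo + margin, hi - margin - K_NA_MASS_DIFF, config.min_spacing
    )

    # Choose anchors whose K+ partner does not collide with an existing center.
    partner = np.full(n, -1, dtype=np.int64)
    mz = np.empty(n)
    mz[:n_anchor] = centers
    order = rng.permutation(n_anchor)
    placed = n_anchor
    existing = np.sort(centers)
    extra: list[float] = []
    for a in order:
        if placed >= n:
            break
        cand = centers[a] + K_NA_MASS_DIFF
        pool = np.sort(np.concatenate([existing, np.asarray(extra)])) if extra else existing
        j = np.searchsorted(pool, cand)
        left_ok = j == 0 or cand - pool[j - 1] >= config.min_spacing
        right_ok = j == len(pool) or pool[j] - cand >= config.min_spacing
        if left_ok and right_ok:
            mz[placed] = cand
            partner[a] = placed
            partner[placed] = a
            extra.append(cand)
            placed += 1
    if placed < n:
        raise ValueError(
            f"infeasible packing: could only place {placed} of {n} species with "
            f"min_spacing {config.min_spacing:g} Da and adduct_fraction "
            f"{config.adduct_fraction:g} in the axis range"
        )

    base_log = rng.normal(config.base_log_mean, config.base_log_sd, size=n)
    # K+ adducts of the same analyte: share abundance, somewhat less efficient
    is_k = partner >= 0
    k_idx = np.flatnonzero(is_k & (np.arange(n) >= n_anchor))
    base_log[k_idx] = base_log[partner[k_idx]] + rng.normal(-0.5, 0.2, size=len(k_idx))

    informative = np.zeros(n, dtype=bool)
    fold_change = np.ones(n)
    if config.n_informative > 0:
        unpaired = np.flatnonzero(partner < 0)
        if len(unpaired) < config.n_informative:
            raise ValueError("not enough unpaired species to host informative markers")
        chosen = rng.choice(unpaired, size=config.n_informative, replace=False)
        informative[chosen] = True
        flo, fhi = config.fold_change_range
        fold_change[chosen] = rng.uniform(flo, fhi, size=config.n_informative)

    # Sort by m/z, remapping partner indices
    idx = np.argsort(mz)
    inv = np.empty(n, dtype=np.int64)
    inv[idx] = np.arange(n)
    partner_sorted = np.where(partner[idx] >= 0, inv[partner[idx]], -1)
    return PeakCatalog(
        mz_center=mz[idx],
        base_log_intensity=base_log[idx],
        adduct_partner=partner_sorted,
        informative=informative[idx],
        fold_change=fold_change[idx],
        config=config,
    )


def _sample_areas(
    catalog: PeakCatalog, group: str, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample peak areas: log-normal jitter, adduct-correlated, fold changes."""
    cfg = catalog.config
    n = len(catalog)
    eps_own = rng.normal(0.0, 1.0, size=n)
    eps_shared = rng.normal(0.0, 1.0, size=n)
    paired = catalog.adduct_partner >= 0
    # one shared draw per analyte pair: copy the lower index's draw to both
    p = catalog.adduct_partner
    lower = paired & (np.arange(n) < p)
    eps_shared[p[lower]] = eps_shared[lower]
    rho = cfg.adduct_rho
    eps = np.where(
        paired,
        rho * eps_shared + np.sqrt(1 - rho**2) * eps_own,
        eps_own,
    )
    log_area = catalog.base_log_intensity + cfg.peak_jitter_sd * eps
    if group == "case":
        log_area = log_area + np.log(catalog.fold_change)
    return np.exp(log_area)


def generate_spectrum(
    catalog: PeakCatalog,
    group: str,
    sample_scale: float = 1.0,
    seed: int | np.random.SeedSequence | None = 0,
    sample_id: str = "sample",
):
    """Render one profile spectrum for a sample of the given group.

    ``sample_scale`` multiplies the whole signal (global intensity scale);
    informative species are additionally scaled by their fold change when
    ``group == "case"``. Returns a :class:`smfdiag.preprocess.RawSpectrum`.
    """
    from .preprocess import RawSpectrum  # local import to avoid a cycle

    if group not in ("case", "control"):
        raise ValueError("group must be 'case' or 'control'")
    if sample_scale <= 0:
        raise ValueError("sample_scale must be positive")
    cfg = catalog.config
    rng = np.random.default_rng(seed)
    mz = cfg.mz_axis
    step = mz[1] - mz[0]
    sigma = cfg.peak_sigma

    areas = _sample_areas(catalog, group, rng)
    heights = areas / (sigma * np.sqrt(2 * np.pi))

    intensity = np.zeros(cfg.axis_points)
    halfw = max(1, int(np.ceil(5 * sigma / step)))
    centers_idx = np.searchsorted(mz, catalog.mz_center)
    offsets = np.arange(-halfw, halfw + 1)
    win_idx = centers_idx[:, None] + offsets[None, :]
    np.clip(win_idx, 0, cfg.axis_points - 1, out=win_idx)
    win_mz = mz[win_idx]
    contrib = heights[:, None] * np.exp(
        -0.5 * ((win_mz - catalog.mz_center[:, None]) / sigma) ** 2
    )
    np.add.at(intensity, win_idx.ravel(), contrib.ravel())

    lo = cfg.mz_range[0]
    if cfg.baseline_amplitude > 0:
        intensity += cfg.baseline_amplitude * np.exp(-(mz - lo) / cfg.baseline_decay)
    intensity *= sample_scale
    if cfg.noise_sd > 0:
        intensity += np.clip(rng.normal(0.0, cfg.noise_sd, size=cfg.axis_points), 0, None)
    return RawSpectrum(mz=mz, intensity=intensity, sample_id=sample_id)


def _cohort_plan(config: SimConfig):
    catalog = build_catalog(config)
    ss = np.random.SeedSequence([config.seed, 0xC040])
    n = config.n_case + config.n_control
    children = ss.spawn(n + 1)
    scale_rng = np.random.default_rng(children[0])
    log_sd = np.sqrt(np.log1p(config.sample_cv**2))
    scales = np.exp(scale_rng.normal(-0.5 * log_sd**2, log_sd, size=n))
    groups = ["case"] * config.n_case + ["control"] * config.n_control
    ids = [f"case_{i:04d}" for i in range(config.n_case)] + [
        f"ctrl_{i:04d}" for i in range(config.n_control)
    ]
    return catalog, groups, ids, scales, children[1:]


def iter_cohort(config: SimConfig):
    """Yield ``(RawSpectrum, group)`` pairs one at a time (memory-friendly).

    Same draws as :func:`generate_cohort` for the same config.
    """
    catalog, groups, ids, scales, seeds = _cohort_plan(config)
    for g, sid, sc, seed in zip(groups, ids, scales, seeds):
        yield generate_spectrum(catalog, g, sc, seed, sid), g


def generate_cohort(config: SimConfig):
    """Generate a full cohort.

    Returns ``(spectra, labels, catalog)`` where ``labels`` is the list of
    group strings aligned with ``spectra`` (cases first), and ``catalog`` is
    the ground truth for test assertions. Fully reproducible from
    ``config.seed``.
    """
    catalog, groups, ids, scales, seeds = _cohort_plan(config)
    spectra = [
        generate_spectrum(catalog, g, sc, seed, sid)
        for g, sid, sc, seed in zip(groups, ids, scales, seeds)
    ]
    return spectra, list(groups), catalog


def bayes_auc(catalog: PeakCatalog) -> float:
    """Closed-form Bayes-optimal AUC of a simulated cohort.

    The informative species differ between groups by a shift log(fc_i) in
    log-area against per-peak log jitter tau, independently across species, so
    the optimal score is Gaussian in both groups and

        AUC* = Phi( sqrt(sum_i (log fc_i / tau)^2) / sqrt(2) ).

    Additive detector noise and peak-detection error are not included, so the
    value is an upper bound that is tight when peak SNR is high.
    """
    tau = catalog.config.peak_jitter_sd
    if tau == 0:
        return 1.0 if np.any(catalog.fold_change != 1.0) else 0.5
    delta = np.sqrt(np.sum((np.log(catalog.fold_change[catalog.informative]) / tau) ** 2))
    return float(norm.cdf(delta / np.sqrt(2)))


def jitter_for_bayes_auc(
    fold_changes: Sequence[float], target_auc: float
) -> float:
    """Per-peak log-jitter sd that sets the cohort's Bayes AUC to ``target_auc``.

    Inverts :func:`bayes_auc` for fixed informative fold changes; used to tune
    cohort difficulty (e.g. to the 0.95 regime of discovery-scale serum
    studies).
    """
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target_auc must lie in (0.5, 1)")
    delta = np.sqrt(2) * norm.ppf(target_auc)
    return float(np.sqrt(np.sum(np.log(np.asarray(fold_changes)) ** 2)) / delta)


def tuned_config(config: SimConfig, target_auc: float) -> SimConfig:
    """Return a copy of ``config`` with peak_jitter_sd tuned so the catalog's
    Bayes AUC equals ``target_auc`` (fold changes are redrawn identically since
    the catalog seed is unchanged)."""
    cat = build_catalog(config)
    tau = jitter_for_bayes_auc(cat.fold_change[cat.informative], target_auc)
    return replace(config, peak_jitter_sd=tau)
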