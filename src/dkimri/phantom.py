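"""Synthetic DWI phantoms and cohorts for end-to-end pipeline testing.

No imaging study data ships with this package, so everything downstream is
exercised on synthetic inputs built here:

* :func:`make_phantom` voxelises ellipsoidal "lesions" on a 3-D grid, draws
  per-voxel (S0, D_app, K_app) from truncated normals, and synthesises the
  noiseless multi-b signal through the kurtosis forward model. A configurable
  fraction of each lesion is converted to a necrotic/cystic core — a
  free-water-like compartment (K = 0, D >= 2.5e-3 mm²/s) that is recorded in
  the ground truth with a negative label but *excluded* from the ROI mask,
  mirroring the analyst's exclusion of cystic and necrotic regions when
  outlining solid tumour.
* :func:`add_rician_noise` applies magnitude-MRI (Rician) noise.
* :func:`simulate_cohort` draws per-patient VOI-level metrics for a
  responder and a non-responder group; the defaults
  (:data:`RESPONDER_GROUP`, :data:`NON_RESPONDER_GROUP`) encode the study
  conditions this package targets: 5 responders vs 10 non-responders with
  K_app 0.69±0.13 vs 0.51±0.11, D_app 1.44±0.30 vs 1.51±0.32 (×1e-3 mm²/s)
  and ADC 1.22±0.24 vs 1.30±0.27 (×1e-3 mm²/s).
* :func:`simulate_histology` attaches cellularity and Ki-67 covariates
  rank-correlated with K_app through a Gaussian copula with an exact
  finite-sample Spearman calibration.

Every stochastic operation is a pure function of its inputs and an explicit
integer seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit, ndtr, ndtri
from scipy.stats import rankdata, truncnorm

from .data import BValueScheme, CohortTable, DWISeries, ROIMask

__all__ = [
    "LesionSpec",
    "PhantomTruth",
    "GroupSpec",
    "RESPONDER_GROUP",
    "NON_RESPONDER_GROUP",
    "DEFAULT_NOISE_SIGMA",
    "make_phantom",
    "add_rician_noise",
    "simulate_cohort",
    "simulate_histology",
    "attach_histology",
    "simulate_study",
    "default_lesions",
    "load_phantom_config",
    "phantom_from_config",
]

# Background compartment: dilute fluid-like tissue with low signal so that
# lesion/background contrast resembles a DWI slab.
BACKGROUND_S0 = 100.0
BACKGROUND_D = 2.0e-3  # mm²/s

# Free-water-like necrotic compartment (free water at 37C is ~3e-3 mm²/s).
NECROTIC_D_RANGE = (2.5e-3, 3.2e-3)

#: Default Rician noise sigma, signal units. With the default lesion
#: S0 = 1000 and D ~ 1.4e-3 mm²/s the signal at b = 100 s/mm² is ~870, so
#: sigma = 17 gives an SNR of ~50 at the lowest b-value.
DEFAULT_NOISE_SIGMA = 17.0

_D_FLOOR = 1e-5  # mm²/s, lower truncation for diffusivity draws


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and parameter distribution of one ellipsoidal lesion."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    d_app_mean: float = 1.44e-3
    d_app_sd: float = 0.30e-3
    k_app_mean: float = 0.69
    k_app_sd: float = 0.13
    s0_mean: float = 1000.0
    necrotic_fraction: float = 0.0

    def __post_init__(self) -> None:
        if len(self.center) != 3 or len(self.radii) != 3:
            raise ValueError("center and radii must be 3-vectors (voxels)")
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"radii must be positive, got {self.radii}")
        if self.d_app_mean <= 0:
            raise ValueError("d_app_mean must be positive")
        if self.k_app_mean < 0:
            raise ValueError("k_app_mean must be non-negative")
        if self.d_app_sd < 0 or self.k_app_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.s0_mean <= 0:
            raise ValueError("s0_mean must be positive")
        if not 0.0 <= self.necrotic_fraction <= 1.0:
            raise ValueError(f"necrotic_fraction must be in [0,1], got {self.necrotic_fraction}")


@dataclass
class PhantomTruth:
    """Ground-truth parameter maps and region labels.

    ``region_labels``: 0 background, k > 0 solid part of lesion k,
    -k necrotic core of lesion k.
    """

    d_app_map: np.ndarray
    k_app_map: np.ndarray
    s0_map: np.ndarray
    region_labels: np.ndarray


@dataclass(frozen=True)
class GroupSpec:
    """Per-patient VOI-level metric distribution for one response group."""

    n_patients: int
    k_app_mean: float
    k_app_sd: float
    d_app_mean: float
    d_app_sd: float
    adc_mean: float
    adc_sd: float

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.k_app_mean < 0 or self.d_app_mean <= 0 or self.adc_mean <= 0:
            raise ValueError("group means must be positive (k_app_mean >= 0)")
        if min(self.k_app_sd, self.d_app_sd, self.adc_sd) < 0:
            raise ValueError("group sds must be non-negative")


#: Study conditions: responder group (n=5), VOI-level metric distributions.
RESPONDER_GROUP = GroupSpec(
    n_patients=5,
    k_app_mean=0.69, k_app_sd=0.13,
    d_app_mean=1.44e-3, d_app_sd=0.30e-3,
    adc_mean=1.22e-3, adc_sd=0.24e-3,
)

#: Study conditions: non-responder group (n=10).
NON_RESPONDER_GROUP = GroupSpec(
    n_patients=10,
    k_app_mean=0.51, k_app_sd=0.11,
    d_app_mean=1.51e-3, d_app_sd=0.32e-3,
    adc_mean=1.30e-3, adc_sd=0.27e-3,
)

#: Default rank-correlation targets between K_app and the histology covariates.
DEFAULT_RHO_CELLULARITY = 0.49
DEFAULT_RHO_KI67 = 0.53


def _draw_truncated_normal(rng, mean, sd, low, size):
    """Normal(mean, sd) truncated below at ``low``; degenerate sd=0 -> constant."""
    if sd == 0:
        return np.full(size, max(float(mean), low))
    a = (low - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def make_phantom(grid_shape, lesions, scheme: BValueScheme, seed: int):
    """Build a noiseless phantom: (DWISeries, PhantomTruth, ROIMask).

    Each lesion's voxels get (S0, D_app, K_app) drawn independently from
    truncated normals (K >= 0, D >= 1e-5 mm²/s); the noiseless signal at
    every scheme b-value follows the kurtosis forward model exactly.
    Background voxels hold a low-signal mono-exponential compartment.
    Necrotic-core voxels are labelled ``-k`` in the truth and omitted from
    the returned ROI mask. Overlapping lesions: the later lesion wins.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3:
        raise ValueError("grid_shape must have 3 dimensions")
    if len(scheme) == 0:
        raise ValueError("empty b-value scheme")
    rng = np.random.default_rng(seed)

    s0_map = np.full(grid_shape, BACKGROUND_S0)
    d_map = np.full(grid_shape, BACKGROUND_D)
    k_map = np.zeros(grid_shape)
    region = np.zeros(grid_shape, dtype=np.int16)

    xx, yy, zz = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    for idx, lesion in enumerate(lesions, start=1):
        c, r = np.asarray(lesion.center, float), np.asarray(lesion.radii, float)
        if np.any(c - r < 0) or np.any(c + r > np.asarray(grid_shape) - 1):
            raise ValueError(f"lesion {idx} extends outside the grid {grid_shape}")
        inside = (
            ((xx - c[0]) / r[0]) ** 2 + ((yy - c[1]) / r[1]) ** 2 + ((zz - c[2]) / r[2]) ** 2
        ) <= 1.0
        coords = np.argwhere(inside)
        n_vox = len(coords)
        if n_vox == 0:
            raise ValueError(f"lesion {idx} covers no voxels")
        sel = tuple(coords.T)
        s0_map[sel] = np.maximum(
            rng.normal(lesion.s0_mean, 0.05 * lesion.s0_mean, n_vox), 1.0
        )
        d_map[sel] = _draw_truncated_normal(rng, lesion.d_app_mean, lesion.d_app_sd, _D_FLOOR, n_vox)
        k_map[sel] = _draw_truncated_normal(rng, lesion.k_app_mean, lesion.k_app_sd, 0.0, n_vox)
        region[sel] = idx
        n_nec = int(round(lesion.necrotic_fraction * n_vox))
        if n_nec > 0:
            nec = coords[rng.choice(n_vox, size=n_nec, replace=False)]
            nsel = tuple(nec.T)
            region[nsel] = -idx
            k_map[nsel] = 0.0
            d_map[nsel] = rng.uniform(*NECROTIC_D_RANGE, size=n_nec)

    b = scheme.as_array()
    signal = s0_map[..., None] * np.exp(
        -b * d_map[..., None] + b**2 * d_map[..., None] ** 2 * k_map[..., None] / 6.0
    )
    series = DWISeries(signal=signal, scheme=scheme)
    truth = PhantomTruth(d_app_map=d_map, k_app_map=k_map, s0_map=s0_map, region_labels=region)
    mask = ROIMask(labels=np.where(region > 0, region, 0).astype(np.int16))
    return series, truth, mask


def add_rician_noise(series: DWISeries, sigma: float, seed: int) -> DWISeries:
    """Magnitude-MRI noise: S -> sqrt((S + e1)^2 + e2^2), e1, e2 ~ N(0, sigma)."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return DWISeries(series.signal.copy(), series.scheme, series.voxel_size)
    rng = np.random.default_rng(seed)
    e1 = rng.normal(0.0, sigma, series.signal.shape)
    e2 = rng.normal(0.0, sigma, series.signal.shape)
    noisy = np.sqrt((series.signal + e1) ** 2 + e2**2)
    return DWISeries(noisy, series.scheme, series.voxel_size)


def simulate_cohort(
    responders: GroupSpec,
    non_responders: GroupSpec,
    seed: int,
    n_unclassified: int = 0,
) -> CohortTable:
    """Draw per-patient VOI metrics for the two response groups.

    K_app draws are truncated at 0 and diffusivities at 1e-5 mm²/s. The
    generating values are stored both as the ``*_voi`` metric columns and as
    ``*_true`` truth columns. Optional ``n_unclassified`` extra patients
    (e.g. an adjuvant-treatment arm never assessed for response) are drawn
    from the two groups' mixture, weighted by group size.
    """
    if n_unclassified < 0:
        raise ValueError("n_unclassified must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []

    def _draw_patients(spec: GroupSpec, n: int, prefix: str, response: str) -> None:
        k = _draw_truncated_normal(rng, spec.k_app_mean, spec.k_app_sd, 0.0, n)
        d = _draw_truncated_normal(rng, spec.d_app_mean, spec.d_app_sd, _D_FLOOR, n)
        adc = _draw_truncated_normal(rng, spec.adc_mean, spec.adc_sd, _D_FLOOR, n)
        for i in range(n):
            rows.append(
                {
                    "patient_id": f"{prefix}{i + 1:02d}",
                    "response_class": response,
                    "adc_voi": adc[i],
                    "d_app_voi": d[i],
                    "k_app_voi": k[i],
                    "adc_true": adc[i],
                    "d_app_true": d[i],
                    "k_app_true": k[i],
                }
            )

    _draw_patients(responders, responders.n_patients, "R", "responder")
    _draw_patients(non_responders, non_responders.n_patients, "N", "non-responder")
    if n_unclassified:
        p_resp = responders.n_patients / (responders.n_patients + non_responders.n_patients)
        for i in range(n_unclassified):
            spec = responders if rng.random() < p_resp else non_responders
            _draw_patients(spec, 1, f"U{i + 1:02d}_", "unclassified")
    # re-key unclassified ids drawn one at a time
    for i, row in enumerate(r for r in rows if r["response_class"] == "unclassified"):
        row["patient_id"] = f"U{i + 1:02d}"
    return CohortTable(pd.DataFrame(rows))


def _expected_sample_spearman(r: float, n: int) -> float:
    """E[sample Spearman] when z2 = r*a + sqrt(1-r^2)*eps against fixed normal scores a.

    With the anchor variable reduced to its normal scores
    ``a_i = ndtri(i/(n+1))`` (fixed, not random), the rank of ``z2_i``
    has expectation ``1 + sum_j Phi(r*(a_i - a_j) / sqrt(2*(1-r^2)))``,
    which plugs into the rank-difference form of the Spearman coefficient.
    This exact finite-n expectation differs appreciably from the asymptotic
    ``(6/pi)*asin(r/2)`` at small n (~0.05 at n=17), so the copula is
    calibrated against it rather than the large-n formula.
    """
    if abs(r) >= 1.0:
        return float(np.sign(r))
    a = ndtri(np.arange(1, n + 1) / (n + 1))
    scale = r / np.sqrt(2.0 * (1.0 - r * r))
    p_less = ndtr((a[:, None] - a[None, :]) * scale)
    np.fill_diagonal(p_less, 0.0)
    expected_rank = 1.0 + p_less.sum(axis=1)
    i = np.arange(1, n + 1)
    return float((12.0 * np.sum(i * expected_rank) - 3.0 * n * (n + 1) ** 2) / (n * (n**2 - 1)))


@lru_cache(maxsize=256)
def _latent_pearson(rho_spearman: float, n: int) -> float:
    """Latent Pearson r whose expected sample Spearman at size n is the target."""
    if not -1.0 <= rho_spearman <= 1.0:
        raise ValueError(f"rho_target must be in [-1, 1], got {rho_spearman}")
    if abs(rho_spearman) == 1.0:
        return float(np.sign(rho_spearman))
    return float(
        brentq(
            lambda r: _expected_sample_spearman(r, n) - rho_spearman,
            -1 + 1e-9, 1 - 1e-9, xtol=1e-12,
        )
    )


def simulate_histology(k_app_values, rho_target, noise_seed: int):
    """Generate (cellularity, ki67_percent) rank-correlated with K_app.

    A Gaussian copula drives the association: the K_app ranks are mapped to
    normal scores z1, each covariate's latent score is
    ``z = r*z1 + sqrt(1-r^2)*eps`` with r calibrated so the *expected sample*
    Spearman correlation at this n equals ``rho_target``, and the latent
    score is pushed through a strictly monotone marginal — log-normal for
    cellularity (cells/µm², median 0.006) and logistic for Ki-67 (percent,
    median 40) — which leaves the rank correlation untouched.

    ``rho_target`` may be a scalar (both covariates) or a
    ``(rho_cellularity, rho_ki67)`` pair.
    """
    k = np.asarray(k_app_values, dtype=float)
    n = k.size
    if n < 3:
        raise ValueError(f"need at least 3 K_app values, got {n}")
    rho_pair = np.broadcast_to(np.asarray(rho_target, dtype=float).ravel(), (2,)) \
        if np.ndim(rho_target) else np.array([float(rho_target)] * 2)
    if np.any(np.abs(rho_pair) > 1):
        raise ValueError(f"rho_target must be in [-1, 1], got {rho_target}")
    rng = np.random.default_rng(noise_seed)
    z1 = ndtri(rankdata(k) / (n + 1))

    def latent(rho: float) -> np.ndarray:
        if abs(rho) == 1.0:
            return np.sign(rho) * z1
        r = _latent_pearson(float(rho), n)
        return r * z1 + np.sqrt(1.0 - r**2) * rng.standard_normal(n)

    cellularity = np.exp(np.log(0.006) + 0.35 * latent(rho_pair[0]))
    ki67 = 100.0 * expit(logit(0.40) + 0.7 * latent(rho_pair[1]))
    return cellularity, ki67


def attach_histology(
    cohort: CohortTable,
    seed: int,
    rho_cellularity: float = DEFAULT_RHO_CELLULARITY,
    rho_ki67: float = DEFAULT_RHO_KI67,
) -> CohortTable:
    """Add copula-generated histology covariate columns to a cohort table."""
    df = cohort.to_frame()
    cellularity, ki67 = simulate_histology(
        df["k_app_voi"].to_numpy(), (rho_cellularity, rho_ki67), seed
    )
    df["cellularity_cells_per_um2"] = cellularity
    df["ki67_percent"] = ki67
    return CohortTable(df)


def simulate_study(
    seed: int,
    responders: GroupSpec = RESPONDER_GROUP,
    non_responders: GroupSpec = NON_RESPONDER_GROUP,
    n_unclassified: int = 2,
    rho_cellularity: float = DEFAULT_RHO_CELLULARITY,
    rho_ki67: float = DEFAULT_RHO_KI67,
) -> CohortTable:
    """Full synthetic study: 5 responders + 10 non-responders + 2 unclassified
    patients, with histology covariates attached."""
    rng = np.random.default_rng(seed)
    cohort = simulate_cohort(
        responders, non_responders, int(rng.integers(2**31)), n_unclassified=n_unclassified
    )
    return attach_histology(cohort, int(rng.integers(2**31)), rho_cellularity, rho_ki67)


def default_lesions() -> list[LesionSpec]:
    """Two solid lesions on the default 48x48x12 grid, one with a necrotic core."""
    return [
        LesionSpec(center=(14, 16, 6), radii=(7, 7, 4), necrotic_fraction=0.0),
        LesionSpec(
            center=(33, 30, 6), radii=(8, 9, 4),
            d_app_mean=1.51e-3, d_app_sd=0.32e-3,
            k_app_mean=0.51, k_app_sd=0.11,
            necrotic_fraction=0.2,
        ),
    ]


DEFAULT_PHANTOM_CONFIG = {
    "grid_shape": [48, 48, 12],
    "bvalues": [100, 500, 900, 1300, 1700],
    "sigma": DEFAULT_NOISE_SIGMA,
    "lesions": None,  # None -> default_lesions()
}


def load_phantom_config(path) -> dict:
    """Read a YAML phantom configuration.

    Schema (all keys optional, defaults shown in DEFAULT_PHANTOM_CONFIG):
      grid_shape: [nx, ny, nz]
      bvalues: [b1, b2, ...]          # s/mm², strictly increasing
      sigma: float                    # Rician noise sd, 0 disables noise
      lesions:                        # list of LesionSpec field mappings
        - center: [x, y, z]
          radii: [rx, ry, rz]
          d_app_mean: 1.44e-3
          d_app_sd: 0.30e-3
          k_app_mean: 0.69
          k_app_sd: 0.13
          s0_mean: 1000.0
          necrotic_fraction: 0.0
    """
    cfg = dict(DEFAULT_PHANTOM_CONFIG)
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(loaded) - set(cfg)
    if unknown:
        raise ValueError(f"unknown phantom config keys: {sorted(unknown)}")
    cfg.update(loaded)
    return cfg


def phantom_from_config(cfg: dict, seed: int):
    """Materialise (noisy_series, noiseless_series, truth, mask) from a config dict."""
    scheme = BValueScheme(cfg["bvalues"])
    lesions = (
        default_lesions()
        if cfg.get("lesions") is None
        else [LesionSpec(**{**spec, "center": tuple(spec["center"]), "radii": tuple(spec["radii"])}) for spec in cfg["lesions"]]
    )
    rng = np.random.default_rng(seed)
    noiseless, truth, mask = make_phantom(cfg["grid_shape"], lesions, scheme, int(rng.integers(2**31)))
    noisy = add_rician_noise(noiseless, float(cfg.get("sigma", 0.0)), int(rng.integers(2**31)))
    return noisy, noiseless, truth, mask
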