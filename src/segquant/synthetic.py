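"""Synthetic test-retest study generator and geometric phantoms.

Emulates the structure of a single-voxel MRS test-retest study in which
each participant is scanned twice and every scan is analysed with three
segmentation methods.  Each participant has a latent "true" voxel
composition (shared participant deviation around the grand mean, plus an
age-linked gray-matter shift, plus small session-to-session noise); each
segmentation method observes that composition with a method-specific
bias (its mean fraction vector) and independent per-analysis noise.
Metabolite/water signal amplitudes are produced from the true
composition through the inverse of the water-referenced quantification
model, so that quantifying with the true composition recovers the true
concentration exactly, while quantifying with each method's fractions
propagates the method biases into the concentration estimates - the
effect the downstream statistics are designed to detect.

Sessions have no systematic effect by construction (an optional offset
exists for power studies).  Fraction noise is additive on the simplex:
deviations are projected onto the sum-zero subspace, so every row sums
to one before the final safeguard renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantification import attenuation_from_config, forward_signal
from .voxel_anatomy import SegmentationMaps, TissueFractions, VoxelGeometry

__all__ = [
    "GeneratorConfig",
    "generate_fractions",
    "generate_signals",
    "generate_study",
    "PhantomStudy",
    "generate_phantom_maps",
]

#: Marginal mean fraction vectors (GM, WM, CSF) per segmentation method;
#: the defaults are the study conditions the generator emulates.
DEFAULT_METHOD_MEANS: dict[str, tuple[float, float, float]] = {
    "ANTS": (0.45, 0.33, 0.22),
    "FSL": (0.43, 0.30, 0.26),
    "SPM": (0.56, 0.27, 0.17),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters for the synthetic generator.

    ``participant_sd`` and ``session_sd`` are per-component SDs of the
    (sum-zero-projected) fraction deviations; ``age_gm_r`` is the target
    participant-level correlation between age and normalized GM, from
    which the age slope is derived.  ``metabolites`` maps metabolite
    name to its true concentration (mM) and optional linear age slope
    (mM per year, around the mean age).
    """

    n_participants: int = 13
    method_means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_METHOD_MEANS)
    )
    participant_sd: float = 0.03
    session_sd: float = 0.01
    age_range: tuple[float, float] = (19.0, 66.0)
    age_gm_r: float = -0.7
    metabolites: dict[str, dict] = field(
        default_factory=lambda: {"tCr": {"true_mM": 7.2, "age_slope_mM_per_yr": 0.0}}
    )
    signal_noise_sd: float = 0.02
    s_h2o: float = 1000.0
    session_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least two participants")
        if self.participant_sd < 0 or self.session_sd < 0:
            raise ValueError("SDs must be nonnegative")
        if self.signal_noise_sd < 0:
            raise ValueError("signal noise SD must be nonnegative")
        if len(self.method_means) < 2:
            raise ValueError("need at least two methods")
        for name, vec in self.method_means.items():
            v = np.asarray(vec, float)
            if v.shape != (3,) or np.any(v < 0) or v.sum() <= 0:
                raise ValueError(f"invalid mean fraction vector for {name}")


def _normalized_means(cfg: GeneratorConfig) -> dict[str, np.ndarray]:
    return {
        name: np.asarray(vec, float) / np.sum(vec)
        for name, vec in sorted(cfg.method_means.items())
    }


def _sum_zero(x: np.ndarray) -> np.ndarray:
    """Project deviation vectors onto the sum-zero subspace of the simplex."""
    return x - x.mean(axis=-1, keepdims=True)


def _age_gm_slope(cfg: GeneratorConfig, true_mean: np.ndarray) -> float:
    """Slope of the GM<->WM age shift targeting the configured age~g r.

    Linearizes g = f_gm/(f_gm+f_wm) at the grand-mean composition: the
    participant deviation u (sum-zero projected, per-component SD
    sigma_P) contributes Var(dg) = grad' Cov(u) grad, and an age shift
    (+b*da, -b*da, 0) contributes (b*sigma_age/T)^2 with T=f_gm+f_wm.
    """
    r = cfg.age_gm_r
    if r == 0 or cfg.participant_sd == 0:
        return 0.0
    if not -1 < r < 1:
        raise ValueError("age_gm_r must lie in (-1, 1)")
    T = true_mean[0] + true_mean[1]
    grad = np.array([true_mean[1] / T**2, -true_mean[0] / T**2, 0.0])
    cov_u = cfg.participant_sd**2 * (np.eye(3) - np.ones((3, 3)) / 3.0)
    var_g = float(grad @ cov_u @ grad)
    sigma_age = (cfg.age_range[1] - cfg.age_range[0]) / np.sqrt(12.0)
    slope_mag = abs(r) / np.sqrt(1 - r**2) * np.sqrt(var_g) * T / sigma_age
    return float(np.sign(r) * slope_mag)


def generate_fractions(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ages and the fraction rows of the study table.

    Returns one row per participant x session x method with the
    method-observed fractions (f_gm/f_wm/f_csf) and the latent true
    composition used for signal generation (f_true_*).
    """
    n = cfg.n_participants
    means = _normalized_means(cfg)
    methods = list(means)
    true_mean = np.mean(list(means.values()), axis=0)

    ages = rng.uniform(*cfg.age_range, size=n)
    slope = _age_gm_slope(cfg, true_mean)
    age_shift = np.zeros((n, 3))
    age_shift[:, 0] = slope * (ages - ages.mean())
    age_shift[:, 1] = -slope * (ages - ages.mean())

    u = _sum_zero(rng.normal(0.0, cfg.participant_sd, size=(n, 3)))
    sess_off = _sum_zero(np.asarray(cfg.session_offset, float))

    rows = []
    raw_vectors = []
    for i in range(n):
        for k, session in enumerate((1, 2)):
            eps_true = _sum_zero(rng.normal(0.0, cfg.session_sd, size=3))
            f_true = true_mean + u[i] + age_shift[i] + eps_true
            if session == 2:
                f_true = f_true + sess_off
            raw_vectors.append(f_true)
            f_true_n = _clip_simplex(f_true)
            for method in methods:
                eps = _sum_zero(rng.normal(0.0, cfg.session_sd, size=3))
                f_obs = means[method] + u[i] + age_shift[i] + eps
                if session == 2:
                    f_obs = f_obs + sess_off
                raw_vectors.append(f_obs)
                f_obs_n = _clip_simplex(f_obs)
                rows.append({
                    "participant": f"P{i + 1:02d}",
                    "age": float(ages[i]),
                    "session": session,
                    "method": method,
                    "f_gm": f_obs_n[0], "f_wm": f_obs_n[1], "f_csf": f_obs_n[2],
                    "f_true_gm": f_true_n[0], "f_true_wm": f_true_n[1],
                    "f_true_csf": f_true_n[2],
                })
    raw = np.asarray(raw_vectors)
    bad = np.mean(np.any(raw < 0, axis=1))
    if bad > 0.01:
        raise ValueError(
            f"{bad:.1%} of draws leave the simplex before normalization; "
            "reduce participant_sd/session_sd"
        )
    return pd.DataFrame(rows)


def _clip_simplex(v: np.ndarray) -> np.ndarray:
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def generate_signals(
    fractions: pd.DataFrame,
    cfg: GeneratorConfig,
    quant_cfg: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Attach signal amplitudes and true concentrations per metabolite.

    Amplitudes come from the inverse quantification model evaluated at
    each row's *true* composition, times per-row multiplicative noise
    exp(eps), eps ~ N(0, sigma^2).  The table is expanded to one row per
    metabolite.
    """
    if cfg.signal_noise_sd < 0:
        raise ValueError("signal noise SD must be nonnegative")
    out_rows = []
    mean_age = float(fractions["age"].mean())
    for met, spec in sorted(cfg.metabolites.items()):
        att, _, k = attenuation_from_config(quant_cfg, metabolite=met)
        base = float(spec["true_mM"])
        slope = float(spec.get("age_slope_mM_per_yr", 0.0))
        for _, row in fractions.iterrows():
            true_c = base + slope * (row["age"] - mean_age)
            if true_c <= 0:
                raise ValueError("age slope drives true concentration nonpositive")
            f_true = TissueFractions(
                row["f_true_gm"], row["f_true_wm"], row["f_true_csf"]
            )
            sig = forward_signal(true_c, f_true, att, k, cfg.s_h2o)
            noise = np.exp(rng.normal(0.0, cfg.signal_noise_sd))
            out_rows.append(dict(row) | {
                "metabolite": met,
                "s_met": sig.s_met * noise,
                "s_h2o": cfg.s_h2o,
                "true_conc_mM": true_c,
            })
    return pd.DataFrame(out_rows)


def generate_study(
    cfg: GeneratorConfig, quant_cfg: dict, seed: int
) -> pd.DataFrame:
    """Full synthetic study table; identical seed gives identical output."""
    rng = np.random.default_rng(seed)
    fractions = generate_fractions(cfg, rng)
    return generate_signals(fractions, cfg, quant_cfg, rng)


@dataclass(frozen=True)
class PhantomStudy:
    """Probability-map phantom with analytically known box fractions.

    GM fills world x < ``split_x_mm`` (optionally with a logistic
    interface profile of width ``smoothing_mm``), WM fills the rest, and
    a CSF slab occupies world z >= ``csf_z_mm``.  The grid is centered
    on the world origin.
    """

    maps: SegmentationMaps
    split_x_mm: float
    smoothing_mm: float
    csf_z_mm: float
    spacing_mm: float

    def analytic_fractions(self, geom: VoxelGeometry) -> TissueFractions:
        """Exact tissue fractions of the field within the MRS box.

        Closed form for axis-aligned boxes; for oblique boxes only the
        symmetric case (interface plane through the box center, box
        clear of the CSF slab) is available.
        """
        aligned = np.allclose(np.abs(geom.orientation), np.eye(3), atol=1e-12)
        c, e = geom.center_mm, geom.edge_mm
        if not aligned:
            z_max = _max_extent(geom, axis=2)
            if abs(c[0] - self.split_x_mm) < 1e-9 and c[2] + z_max <= self.csf_z_mm:
                return TissueFractions(0.5, 0.5, 0.0)
            raise ValueError("no analytic fraction for this oblique geometry")
        x_lo, x_hi = c[0] - e[0] / 2, c[0] + e[0] / 2
        z_lo, z_hi = c[2] - e[2] / 2, c[2] + e[2] / 2
        gm_share = _mean_gm_profile(x_lo, x_hi, self.split_x_mm, self.smoothing_mm)
        csf = np.clip((z_hi - self.csf_z_mm) / e[2], 0.0, 1.0)
        return TissueFractions(
            float(gm_share * (1 - csf)), float((1 - gm_share) * (1 - csf)), float(csf)
        )


def _max_extent(geom: VoxelGeometry, axis: int) -> float:
    """Half-extent of the oriented box along a world axis."""
    return float(np.sum(np.abs(geom.orientation[:, axis]) * geom.edge_mm / 2.0))


def _mean_gm_profile(a: float, b: float, split: float, w: float) -> float:
    """Mean of the GM interface profile over [a, b].

    Sharp step for w=0; logistic sigma((split-x)/w) otherwise, using
    integral sigma((s-x)/w) dx = w*[softplus((s-a)/w) - softplus((s-b)/w)].
    """
    if w == 0:
        return float(np.clip((split - a) / (b - a), 0.0, 1.0))
    sp = lambda t: np.logaddexp(0.0, t)  # noqa: E731
    return float(w * (sp((split - a) / w) - sp((split - b) / w)) / (b - a))


def generate_phantom_maps(
    grid_shape: tuple[int, int, int] = (40, 40, 40),
    spacing_mm: float = 2.0,
    split_x_mm: float = 0.0,
    smoothing_mm: float = 0.0,
    csf_z_mm: float = np.inf,
) -> PhantomStudy:
    """Build a planar GM/WM phantom with an optional CSF slab.

    The grid is centered on the world origin with an axis-aligned
    affine, so a box centered at the origin sees the interface through
    its center.  Fields are sampled at image-voxel centers.
    """
    shape = tuple(int(s) for s in grid_shape)
    if min(shape) < 8:
        raise ValueError("grid must be at least 8 voxels per axis")
    affine = np.diag([spacing_mm] * 3 + [1.0])
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * spacing_mm
    idx = np.indices(shape, dtype=float)
    x = idx[0] * spacing_mm + affine[0, 3]
    z = idx[2] * spacing_mm + affine[2, 3]
    if smoothing_mm == 0:
        gm_profile = (x < split_x_mm).astype(float)
    else:
        gm_profile = 1.0 / (1.0 + np.exp(-(split_x_mm - x) / smoothing_mm))
    csf = (z >= csf_z_mm).astype(float)
    maps = SegmentationMaps(
        prob_gm=gm_profile * (1 - csf),
        prob_wm=(1 - gm_profile) * (1 - csf),
        prob_csf=csf,
        affine=affine,
    )
    return PhantomStudy(
        maps=maps,
        split_x_mm=split_x_mm,
        smoothing_mm=smoothing_mm,
        csf_z_mm=csf_z_mm,
        spacing_mm=spacing_mm,
    )
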