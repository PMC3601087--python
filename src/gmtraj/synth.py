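"""Synthetic phantom cohorts with known covariate-linked grey-matter effects.

The generator emulates the *output* of a VBM preprocessing chain — non-negative
modulated GM maps in a common space, smoothed with an isotropic Gaussian — for
a two-group cross-sectional study: abstinent cocaine-dependent (CD) subjects
whose regional GM depends linearly on weeks of abstinence / years of use, and
drug-naive controls at a flat baseline.  The phantom support is a centered
ellipsoid; each effect is a sphere inside it where CD maps get

    cd_offset + slope * covariate(subject)

added to the baseline, so the CD trend line can start below the control mean
and cross it at a known covariate value (-cd_offset/slope).  Subject noise is
white Gaussian smoothed with the same sigma as the data smoothing, applied
before the final clip at zero.  Ground-truth effect masks are returned so that
recovery tests never have to re-derive them.

Default covariate ranges mirror the study population: abstinence 1-102 weeks,
years of use 0.3-24, age 20-55, sampled uniformly (only range and mean are
reported for the real cohort; uniform is the least-committal choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .volume_io import GMMap, read_gm_map, write_stat_map

__all__ = [
    "EffectSpec",
    "CohortConfig",
    "generate_covariates",
    "generate_gm_maps",
    "write_cohort",
    "load_cohort",
    "support_mask",
    "sphere_mask",
    "default_abstinence_effect",
]

VALID_TERMS = ("abstinence_weeks", "years_use", "age")

DEFAULT_COVARIATE_RANGES = {
    "abstinence_weeks": (1.0, 102.0),
    "years_use": (0.3, 24.0),
    "age": (20.0, 55.0),
}


@dataclass(frozen=True)
class EffectSpec:
    """A spherical region whose CD grey matter depends linearly on a covariate.

    ``cd_offset`` is the CD-group GM offset (relative to baseline) at
    covariate = 0; a negative offset plus a positive slope yields a trajectory
    that starts below the control mean and crosses it at -cd_offset/slope.
    """

    center_voxel: tuple[int, int, int]
    radius_mm: float
    term: str
    slope: float
    cd_offset: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "center_voxel", tuple(int(c) for c in self.center_voxel))
        if self.radius_mm <= 0:
            raise ValueError(f"radius_mm must be > 0, got {self.radius_mm}")
        if self.term not in VALID_TERMS:
            raise ValueError(f"unknown term {self.term!r}; expected one of {VALID_TERMS}")

    @property
    def true_crossover(self) -> float:
        """Covariate value where the noiseless CD line meets the control baseline."""
        if self.slope == 0:
            return float("nan")
        return -self.cd_offset / self.slope


@dataclass
class CohortConfig:
    """Everything needed to generate one phantom cohort reproducibly."""

    n_cd: int = 43
    n_ctrl: int = 43
    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 2.0
    baseline_gm: float = 0.5
    noise_sd: float = 0.03
    smooth_sigma_mm: float = 2.0
    covariate_ranges: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_RANGES))
    effects: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_cd <= 0 or self.n_ctrl <= 0:
            raise ValueError("subject counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.covariate_ranges = {
            name: (float(lo), float(hi)) for name, (lo, hi) in self.covariate_ranges.items()
        }
        for name, (lo, hi) in self.covariate_ranges.items():
            if not lo < hi:
                raise ValueError(f"degenerate range for {name}: ({lo}, {hi})")
        self.effects = tuple(
            e if isinstance(e, EffectSpec) else EffectSpec(**e) for e in self.effects
        )

    @property
    def affine(self) -> np.ndarray:
        """RAS+ affine with the grid centered on the mm origin."""
        vs = self.voxel_size_mm
        aff = np.diag([vs, vs, vs, 1.0])
        aff[:3, 3] = -vs * (np.asarray(self.grid_shape) - 1) / 2.0
        return aff

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effects"] = [
            {**asdict(e), "center_voxel": list(e.center_voxel)} for e in self.effects
        ]
        d["grid_shape"] = list(self.grid_shape)
        d["covariate_ranges"] = {k: list(v) for k, v in self.covariate_ranges.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["grid_shape"] = tuple(d.get("grid_shape", (40, 48, 40)))
        d["effects"] = tuple(EffectSpec(center_voxel=tuple(e["center_voxel"]),
                                        radius_mm=e["radius_mm"], term=e["term"],
                                        slope=e["slope"], cd_offset=e.get("cd_offset", 0.0))
                             for e in d.get("effects", ()))
        return cls(**d)


def default_abstinence_effect(config: CohortConfig | None = None) -> EffectSpec:
    """The canonical recovery phantom: GM gained at 0.002/week of abstinence,
    starting 0.05 GM-units below the control baseline (crossover at 25 weeks)."""
    shape = config.grid_shape if config is not None else (40, 48, 40)
    center = tuple(int(s // 2) for s in shape)
    return EffectSpec(center_voxel=center, radius_mm=8.0, term="abstinence_weeks",
                      slope=0.002, cd_offset=-0.05)


def support_mask(config: CohortConfig) -> np.ndarray:
    """Centered ellipsoid phantom support, semi-axes 0.4 x grid extent."""
    shape = np.asarray(config.grid_shape, dtype=float)
    semi = 0.4 * shape
    center = (shape - 1) / 2.0
    grids = np.ogrid[tuple(slice(0, int(s)) for s in config.grid_shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def sphere_mask(grid_shape, center_voxel, radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Binary sphere of given physical radius around a voxel center."""
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    r2 = sum(((g - c) * voxel_size_mm) ** 2 for g, c in zip(grids, center_voxel))
    return r2 <= radius_mm**2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def generate_covariates(config: CohortConfig) -> pd.DataFrame:
    """Sample the covariate table: controls + CD, uniform within ranges.

    Controls carry only age; abstinence and years of use are CD-only (NaN for
    controls).  Deterministic given ``config.seed``.
    """
    rng = _rng(config.seed, 0)
    n = config.n_cd + config.n_ctrl
    ids = [f"ctrl-{i+1:03d}" for i in range(config.n_ctrl)] + [
        f"cd-{i+1:03d}" for i in range(config.n_cd)
    ]
    groups = ["control"] * config.n_ctrl + ["CD"] * config.n_cd
    lo, hi = config.covariate_ranges["age"]
    age = rng.uniform(lo, hi, size=n)
    abst = np.full(n, np.nan)
    years = np.full(n, np.nan)
    lo, hi = config.covariate_ranges["abstinence_weeks"]
    abst[config.n_ctrl:] = rng.uniform(lo, hi, size=config.n_cd)
    lo, hi = config.covariate_ranges["years_use"]
    years[config.n_ctrl:] = rng.uniform(lo, hi, size=config.n_cd)
    return pd.DataFrame(
        {
            "subject": ids,
            "group": groups,
            "age": age,
            "abstinence_weeks": abst,
            "years_use": years,
        }
    )


def generate_gm_maps(cohort: pd.DataFrame, config: CohortConfig):
    """Render one GM map per subject plus ground-truth effect masks.

    map = clip(baseline * support + sum_effects (cd_offset + slope*cov) * sphere
               + smooth(white noise) * support, 0)

    Controls receive baseline + noise only.  Returns ``(maps, truth)`` where
    ``truth`` is a list of (EffectSpec, binary mask) pairs.
    """
    support = support_mask(config)
    affine = config.affine
    truth = []
    for eff in config.effects:
        m = sphere_mask(config.grid_shape, eff.center_voxel, eff.radius_mm, config.voxel_size_mm)
        if not np.all(support[m]):
            raise ValueError(f"effect sphere at {eff.center_voxel} extends outside the phantom support")
        truth.append((eff, m))

    sigma_vox = config.smooth_sigma_mm / config.voxel_size_mm
    rng = _rng(config.seed, 1)
    base = config.baseline_gm * support.astype(float)
    maps = []
    for row in cohort.itertuples(index=False):
        vol = base.copy()
        if row.group == "CD":
            for eff, m in truth:
                cov = getattr(row, eff.term)
                vol[m] += eff.cd_offset + eff.slope * cov
        if config.noise_sd > 0:
            noise = rng.standard_normal(config.grid_shape) * config.noise_sd
            noise = gaussian_filter(noise, sigma=sigma_vox)
            vol += noise * support
        np.clip(vol, 0, None, out=vol)
        maps.append(GMMap(data=vol, affine=affine.copy(), subject_id=row.subject))
    return maps, truth


def write_cohort(cohort: pd.DataFrame, maps, out_dir, config: CohortConfig | None = None) -> Path:
    """Write NIfTI maps, the covariate CSV, and a YAML manifest; returns manifest path."""
    out = Path(str(out_dir))
    out.mkdir(parents=True, exist_ok=True)
    if len(maps) != len(cohort):
        raise ValueError(f"{len(maps)} maps for {len(cohort)} cohort rows")
    files = {}
    for m in maps:
        fname = f"{m.subject_id}_gm.nii.gz"
        write_stat_map(m.data, m.affine, out / fname)
        files[m.subject_id] = fname
    cov_path = out / "covariates.csv"
    cohort[["subject", "group", "age", "abstinence_weeks", "years_use"]].to_csv(
        cov_path, index=False
    )
    manifest = {
        "covariates": cov_path.name,
        "n_subjects": int(len(cohort)),
        "maps": files,
        "config": config.to_dict() if config is not None else None,
    }
    mpath = out / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def load_cohort(manifest_path):
    """Reload a written cohort: (covariate table, list of GMMap in table order)."""
    mpath = Path(str(manifest_path))
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)
    root = mpath.parent
    cohort = pd.read_csv(root / manifest["covariates"])
    maps = [
        read_gm_map(root / manifest["maps"][sid], subject_id=sid)
        for sid in cohort["subject"]
    ]
    return cohort, maps
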