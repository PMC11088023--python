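"""Synthetic dynamic phantoms and lesion-level cohorts with known truth.

No imaging data accompany the clinical study this package models, so every
downstream stage is exercised against two generators:

* :func:`make_phantom` — a digital chest stand-in: background tissue, a
  spherical lesion and an aortic cylinder, each voxel following the
  two-tissue forward model (the aorta carries the blood curve directly),
  with optional Gaussian post-reconstruction noise whose variance scales
  inversely with frame duration.
* :func:`simulate_cohort` — lesion-level tables whose per-group marginals
  are calibrated to printed clinical summaries: log-normal models for
  parameters reported as median [IQR], truncated-normal models (moment
  matched after truncation at zero) for parameters reported as mean +/- SD.

Group sizes and calibration values default to the modelled study: 23
benign / 124 malignant lesions; 93 adenocarcinoma (AC) / 17 squamous (SCC);
31 EGFR-mutated / 17 EGFR wild-type among the 48 tested AC patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .framing import DynamicImage, FrameSchedule, ValidationError, build_frame_schedule, DEFAULT_PROTOCOL
from .input_function import InputFunction, cumulative_integrals, feng_aif
from .kinetics import KineticParams, simulate_tissue_tac
from .lesion import COHORT_COLUMNS

__all__ = [
    "PhantomSpec",
    "GroupSpec",
    "CohortSpec",
    "Dist",
    "make_phantom",
    "simulate_cohort",
    "benign_ki_range_cohort",
    "malignancy_cohort_spec",
    "histology_cohort_spec",
    "egfr_cohort_spec",
    "NOISE_ALPHA",
]

# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

#: noise scale per level; sigma_i = alpha * sqrt(max(C_i, C_floor)/dt_i_min).
#: "moderate" is calibrated so late-frame lesion-voxel CoV is ~10% for the
#: default lesion truth under the packaged input function (see docs).
NOISE_ALPHA = {"none": 0.0, "low": 0.385, "moderate": 0.77, "high": 1.54}

_NOISE_FLOOR_KBQ_ML = 0.1


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, kinetics and noise of the digital phantom."""

    shape: tuple[int, int, int] = (32, 32, 16)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)  # mm
    background: KineticParams = field(
        default_factory=lambda: KineticParams(0.05, 0.40, 0.005)
    )
    lesion_center: tuple[int, int, int] = (21, 21, 8)
    lesion_radius_mm: float = 10.0
    lesion: KineticParams = field(
        default_factory=lambda: KineticParams(0.12, 0.25, 0.06)
    )
    aorta_center_xy: tuple[int, int] = (8, 8)
    aorta_radius_mm: float = 15.0  # ascending aorta is ~30 mm across
    noise_level: str = "none"
    injected_dose_MBq: float = 264.8
    body_weight_kg: float = 65.0

    def __post_init__(self) -> None:
        if self.noise_level not in NOISE_ALPHA:
            raise ValidationError(f"noise_level must be one of {sorted(NOISE_ALPHA)}")
        if self.lesion_radius_mm <= max(self.spacing) or self.aorta_radius_mm <= max(self.spacing[:2]):
            raise ValidationError("structure radii must exceed the voxel spacing")


def _phantom_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = spec.lesion_center
    d2 = ((ii - cx) * sx) ** 2 + ((jj - cy) * sy) ** 2 + ((kk - cz) * sz) ** 2
    lesion = d2 <= spec.lesion_radius_mm**2
    ax, ay = spec.aorta_center_xy
    a2 = ((ii - ax) * sx) ** 2 + ((jj - ay) * sy) ** 2
    aorta = a2 <= spec.aorta_radius_mm**2
    if not lesion.any() or not aorta.any():
        raise ValidationError("lesion or aorta mask is empty; check geometry")
    if np.any(lesion & aorta):
        raise ValidationError("lesion and aorta overlap")
    edge = (
        lesion[0].any() or lesion[-1].any()
        or lesion[:, 0].any() or lesion[:, -1].any()
        or lesion[:, :, 0].any() or lesion[:, :, -1].any()
    )
    if edge:
        raise ValidationError("lesion touches the grid boundary")
    return lesion, aorta


def _frame_averaged_cp(f: InputFunction, s: FrameSchedule) -> np.ndarray:
    i1_end, _ = cumulative_integrals(f, s.end_min)
    i1_start, _ = cumulative_integrals(f, s.start_min)
    return (i1_end - i1_start) / s.duration_min


def make_phantom(
    spec: PhantomSpec,
    f: InputFunction | None = None,
    s: FrameSchedule | None = None,
    seed: int = 0,
) -> tuple[DynamicImage, dict]:
    """Build a dynamic phantom and its ground-truth description.

    Every voxel of a structure carries that structure's noiseless TAC
    (aorta voxels carry the frame-averaged blood curve); noise is additive
    zero-mean Gaussian with per-frame sigma alpha*sqrt(max(C, floor)/dt).
    Identical spec + seed reproduce the image bit for bit.

    Returns ``(image, truth)`` where ``truth`` holds per-structure kinetic
    parameters and boolean masks — everything needed to score a recovery
    experiment downstream.
    """
    if f is None:
        f = feng_aif()
    if s is None:
        s = build_frame_schedule(DEFAULT_PROTOCOL)
    lesion_mask, aorta_mask = _phantom_masks(spec)
    bg_tac = simulate_tissue_tac(spec.background, f, s).values
    lesion_tac = simulate_tissue_tac(spec.lesion, f, s).values
    aorta_tac = _frame_averaged_cp(f, s)

    voxels = np.empty((*spec.shape, s.n_frames))
    voxels[...] = bg_tac
    voxels[lesion_mask] = lesion_tac
    voxels[aorta_mask] = aorta_tac

    alpha = NOISE_ALPHA[spec.noise_level]
    if alpha > 0:
        rng = np.random.default_rng(seed)
        sigma = alpha * np.sqrt(
            np.maximum(voxels, _NOISE_FLOOR_KBQ_ML) / s.duration_min
        )
        voxels = voxels + rng.normal(0.0, 1.0, voxels.shape) * sigma

    affine = np.diag([*spec.spacing, 1.0])
    img = DynamicImage(
        voxels=voxels,
        spacing=spec.spacing,
        affine=affine,
        schedule=s,
        meta={
            "injected_dose_MBq": spec.injected_dose_MBq,
            "body_weight_kg": spec.body_weight_kg,
        },
    )
    truth = {
        "lesion": {
            "k1": spec.lesion.k1, "k2": spec.lesion.k2, "k3": spec.lesion.k3,
            "ki": spec.lesion.ki, "center": list(spec.lesion_center),
            "radius_mm": spec.lesion_radius_mm,
        },
        "background": {
            "k1": spec.background.k1, "k2": spec.background.k2,
            "k3": spec.background.k3, "ki": spec.background.ki,
        },
        "noise_level": spec.noise_level,
        "seed": seed,
        "lesion_mask": lesion_mask,
        "aorta_mask": aorta_mask,
    }
    return img, truth


def save_phantom_truth(truth: dict, path: str | Path) -> None:
    """Write the ground-truth sidecar as JSON (masks as voxel index lists)."""
    out = {k: v for k, v in truth.items() if not isinstance(v, np.ndarray)}
    for key in ("lesion_mask", "aorta_mask"):
        out[key + "_voxels"] = np.argwhere(truth[key]).tolist()
        out[key + "_shape"] = list(truth[key].shape)
    Path(path).write_text(json.dumps(out))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dist:
    """Marginal distribution calibrated from a printed group summary.

    ``lognormal`` from median [q1; q3] (location ln(median), scale
    ln(q3/q1)/(2*0.6745)); ``truncnormal`` from mean +/- SD with the parent
    normal moment-matched so the zero-truncated distribution reproduces the
    printed moments exactly.
    """

    kind: str
    a: float
    b: float
    c: float = 0.0  # q3 for lognormal; unused for truncnormal

    @staticmethod
    def lognormal(median: float, q1: float, q3: float) -> "Dist":
        if not 0 < q1 < median < q3:
            raise ValidationError("lognormal calibration requires 0 < q1 < median < q3")
        return Dist("lognormal", median, q1, q3)

    @staticmethod
    def truncnormal(mean: float, sd: float) -> "Dist":
        if mean <= 0 or sd <= 0:
            raise ValidationError("truncnormal calibration requires positive mean and SD")
        return Dist("truncnormal", mean, sd)

    def frozen(self):
        if self.kind == "lognormal":
            mu = np.log(self.a)
            sigma = np.log(self.c / self.b) / (2 * stats.norm.ppf(0.75))
            return stats.lognorm(s=sigma, scale=np.exp(mu))
        if self.kind == "truncnormal":
            loc, scale = _truncnorm_parent(self.a, self.b)
            return stats.truncnorm(a=-loc / scale, b=np.inf, loc=loc, scale=scale)
        raise ValidationError(f"unknown distribution kind {self.kind!r}")


@lru_cache(maxsize=64)
def _truncnorm_parent(mean: float, sd: float) -> tuple[float, float]:
    """Parent (loc, scale) such that the zero-truncated normal has the
    requested mean and SD."""

    def moments(x):
        loc, scale = x
        if scale <= 0:
            return [1e6, 1e6]
        d = stats.truncnorm(a=-loc / scale, b=np.inf, loc=loc, scale=scale)
        m, v = d.stats(moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.root(moments, x0=[mean, sd], method="hybr")
    if not sol.success:  # pragma: no cover - hybr converges for sane inputs
        raise RuntimeError(f"truncated-normal calibration failed: {sol.message}")
    return float(sol.x[0]), float(sol.x[1])


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: size, class labels and per-parameter marginals."""

    name: str
    n: int
    labels: tuple[tuple[str, str], ...]  # e.g. (("malignancy", "benign"),)
    params: tuple[tuple[str, Dist], ...]  # must include suv_max, k1, k2, k3, ki
    diameters: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("group size must be >= 1")
        names = {k for k, _ in self.params}
        missing = {"suv_max", "k1", "k2", "k3", "ki"} - names
        if missing:
            raise ValidationError(f"group {self.name!r} missing marginals: {sorted(missing)}")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    rank_corr: float = 0.0  # Gaussian-copula correlation between marginals

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("cohort spec needs at least one group")
        if not -0.99 <= self.rank_corr <= 0.99:
            raise ValidationError("rank_corr must lie in [-0.99, 0.99]")


# Printed group summaries used as default calibration targets ---------------

_MALIGNANT_PARAMS = (
    ("suv_max", Dist.lognormal(9.35, 5.60, 13.10)),
    ("k1", Dist.lognormal(0.1239, 0.0957, 0.1910)),
    ("k2", Dist.lognormal(0.2494, 0.1418, 0.4353)),
    ("k3", Dist.lognormal(0.0632, 0.0344, 0.0888)),
    ("ki", Dist.lognormal(0.0267, 0.0183, 0.0422)),
)

_K1_MALIGNANT = Dist.lognormal(0.1239, 0.0957, 0.1910)


def malignancy_cohort_spec() -> CohortSpec:
    """Default benign/malignant cohort: 23 + 124 lesions."""
    benign = GroupSpec(
        name="benign",
        n=23,
        labels=(("malignancy", "benign"),),
        params=(
            ("suv_max", Dist.lognormal(3.20, 1.85, 6.50)),
            ("k1", Dist.lognormal(0.1661, 0.0974, 0.3561)),
            ("k2", Dist.lognormal(0.4077, 0.3089, 0.9022)),
            ("k3", Dist.lognormal(0.0330, 0.0204, 0.0489)),
            ("ki", Dist.lognormal(0.0102, 0.0069, 0.0142)),
        ),
        diameters=((2.07, 1.16), (1.42, 0.81)),
    )
    malignant = GroupSpec(
        name="malignant",
        n=124,
        labels=(("malignancy", "malignant"),),
        params=_MALIGNANT_PARAMS,
        diameters=((3.68, 1.89), (2.87, 1.43)),
    )
    return CohortSpec(groups=(benign, malignant))


def histology_cohort_spec() -> CohortSpec:
    """Adenocarcinoma vs squamous cohort: 93 AC + 17 SCC lesions.

    K1 was not reported per histology; the malignant-group K1 marginal is
    reused for both.
    """
    ac = GroupSpec(
        name="AC",
        n=93,
        labels=(("malignancy", "malignant"), ("histology", "AC")),
        params=(
            ("suv_max", Dist.lognormal(7.95, 4.30, 11.53)),
            ("k1", _K1_MALIGNANT),
            ("k2", Dist.lognormal(0.2828, 0.1626, 0.5221)),
            ("k3", Dist.lognormal(0.0587, 0.0277, 0.0888)),
            ("ki", Dist.lognormal(0.0247, 0.0145, 0.0351)),
        ),
    )
    scc = GroupSpec(
        name="SCC",
        n=17,
        labels=(("malignancy", "malignant"), ("histology", "SCC")),
        params=(
            ("suv_max", Dist.lognormal(13.80, 12.70, 16.40)),
            ("k1", _K1_MALIGNANT),
            ("k2", Dist.lognormal(0.1987, 0.1263, 0.3012)),
            ("k3", Dist.lognormal(0.0798, 0.0537, 0.0987)),
            ("ki", Dist.lognormal(0.0448, 0.0314, 0.0534)),
        ),
    )
    return CohortSpec(groups=(ac, scc))


def egfr_cohort_spec() -> CohortSpec:
    """EGFR-mutated vs wild-type AC cohort: 31 + 17 lesions.

    Mean +/- SD summaries (truncated-normal models); k2 and K1 were not
    reported per EGFR group, so the AC/malignant marginals are reused.
    """
    k2_ac = Dist.lognormal(0.2828, 0.1626, 0.5221)
    pos = GroupSpec(
        name="EGFR+",
        n=31,
        labels=(("malignancy", "malignant"), ("histology", "AC"), ("egfr", "positive")),
        params=(
            ("suv_max", Dist.truncnormal(9.28, 5.11)),
            ("k1", _K1_MALIGNANT),
            ("k2", k2_ac),
            ("k3", Dist.truncnormal(0.0666, 0.0389)),
            ("ki", Dist.truncnormal(0.0279, 0.0153)),
        ),
    )
    neg = GroupSpec(
        name="EGFR-",
        n=17,
        labels=(("malignancy", "malignant"), ("histology", "AC"), ("egfr", "negative")),
        params=(
            ("suv_max", Dist.truncnormal(12.49, 7.25)),
            ("k1", _K1_MALIGNANT),
            ("k2", k2_ac),
            ("k3", Dist.truncnormal(0.0730, 0.0354)),
            ("ki", Dist.truncnormal(0.0405, 0.0199)),
        ),
    )
    return CohortSpec(groups=(pos, neg))


def _copula_uniforms(rng, n: int, k: int, rho: float) -> np.ndarray:
    """(n, k) uniforms, independent (rho=0) or equicorrelated Gaussian copula."""
    if rho == 0.0:
        return rng.random((n, k))
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(k), cov, size=n)
    return stats.norm.cdf(z)


def simulate_cohort(
    spec: CohortSpec | None = None, seed: int = 0, *, sizes: dict[str, int] | None = None
) -> pd.DataFrame:
    """Draw a lesion-level cohort table from calibrated group marginals.

    SUVmax, K1, k2 and k3 are drawn from their marginals; the raw macro
    Ki = K1*k3/(k2+k3) is then monotonically rescaled (rank-preserving
    quantile map) onto the group's own printed Ki calibration, so the Ki
    marginal matches its target while remaining a monotone function of the
    drawn kinetics.  Deterministic under ``seed``.
    """
    if spec is None:
        spec = malignancy_cohort_spec()
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for grp in spec.groups:
        n = sizes.get(grp.name, grp.n) if sizes else grp.n
        pnames = [k for k, _ in grp.params]
        dists = {k: d.frozen() for k, d in grp.params}
        u = _copula_uniforms(rng, n, len(pnames), spec.rank_corr)
        draws = {k: dists[k].ppf(u[:, j]) for j, k in enumerate(pnames)}
        ki_raw = draws["k1"] * draws["k3"] / (draws["k2"] + draws["k3"])
        order = stats.rankdata(ki_raw, method="ordinal")
        ki = dists["ki"].ppf((order - 0.5) / n)
        labels = dict(grp.labels)
        if grp.diameters is not None:
            (lm, ls), (sm, ss) = grp.diameters
            long_d = stats.truncnorm.rvs(
                -lm / ls, np.inf, loc=lm, scale=ls, size=n, random_state=rng
            )
            short_d = stats.truncnorm.rvs(
                -sm / ss, np.inf, loc=sm, scale=ss, size=n, random_state=rng
            )
        else:
            long_d = short_d = np.full(n, np.nan)
        for i in range(n):
            counter += 1
            rows.append(
                {
                    "lesion_id": f"L{counter:04d}",
                    "suv_max": draws["suv_max"][i],
                    "k1": draws["k1"][i],
                    "k2": draws["k2"][i],
                    "k3": draws["k3"][i],
                    "ki": ki[i],
                    "malignancy": labels.get("malignancy", "malignant"),
                    "histology": labels.get("histology", "none"),
                    "egfr": labels.get("egfr", "untested"),
                    "long_diameter_cm": long_d[i],
                    "short_diameter_cm": short_d[i],
                }
            )
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df.attrs["ki_convention"] = "macro-draw, quantile-matched to printed Ki marginal"
    df.attrs["seed"] = seed
    return df


def benign_ki_range_cohort(n: int, lo: float = 0.0002, hi: float = 0.0246) -> np.ndarray:
    """Deterministic benign Ki stand-in: n values evenly spanning [lo, hi].

    Defaults cover the printed benign net-influx range 0.0002-0.0246
    ml/g/min.
    """
    if n < 2:
        raise ValidationError("need at least 2 values to span a range")
    if not lo < hi:
        raise ValidationError("require lo < hi")
    return np.linspace(lo, hi, n)
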