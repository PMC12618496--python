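"""Synthetic multimodal survival cohorts with known ground truth.

Covariates loosely mimic an adult diffuse-glioma cohort; event times follow
a per-subject Weibull AFT law log lambda_i = beta . x_i + image_effect * z_i
(z = standardized log lesion volume), with independent exponential censoring
whose rate is solved by bisection to hit the target censored fraction, and
MAR missingness whose probability depends only on always-generated
covariates, never on the outcome.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import c_index
from .tabular import PatientRecord

# numeric design codes per variable (centered so coefficients act on
# roughly unit-scale features); positive code = conventionally worse level
_DESIGN = {
    "age": lambda r: (r["age"] - 55.0) / 15.0,
    "sex": lambda r: 0.5 if r["sex"] == "male" else -0.5,
    "kps": lambda r: -(r["kps"] - 65.0) / 20.0,
    "who_grade": lambda r: float(r["who_grade"]) - 3.0,
    "histology": lambda r: {"glioblastoma": 1.0, "astrocytoma": 0.0,
                            "oligodendroglioma": -1.0}[r["histology"]],
    "idh": lambda r: 0.5 if r["idh"] == "wildtype" else -0.5,
    "codeletion_1p19q": lambda r: -0.5 if r["codeletion_1p19q"] == "codeleted" else 0.5,
    "mgmtp": lambda r: 0.5 if r["mgmtp"] == "unmethylated" else -0.5,
    "eor": lambda r: {"gross total": -0.5, "subtotal": 0.0, "biopsy": 0.5}[r["eor"]],
    "radiotherapy": lambda r: -0.5 if r["radiotherapy"] == "received" else 0.5,
    "chemotherapy": lambda r: -0.5 if r["chemotherapy"] == "received" else 0.5,
}

DEFAULT_COEFS = {
    "intercept": float(np.log(24.0)),
    "age": -0.45,
    "kps": -0.40,
    "who_grade": -0.25,
    "histology": -0.30,
    "idh": -0.60,
    "codeletion_1p19q": -0.30,
    "mgmtp": -0.50,
    "eor": -0.40,
    "radiotherapy": -0.30,
    "chemotherapy": -0.30,
}


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 400
    volume_shape: tuple[int, int, int] = (24, 24, 8)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 4.0)
    lesion_radius_range_vox: tuple[float, float] = (2.0, 6.0)
    coef_log_lambda: dict = field(default_factory=lambda: dict(DEFAULT_COEFS))
    image_effect: float = -0.35
    log_rho_true: float = float(np.log(1.8))
    censoring_rate_target: float = 0.30
    missing_rate: dict = field(default_factory=dict)
    mar_strength: float = 0.8
    noise_sd: float = 0.1
    generate_volumes: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (0.0 <= self.censoring_rate_target < 1.0):
            raise ValueError("censoring_rate_target must lie in [0, 1)")
        for var, rate in self.missing_rate.items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"missing rate for {var!r} must lie in [0, 1)")
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape must be positive")


@dataclass
class GroundTruth:
    log_lambda: np.ndarray
    log_rho: np.ndarray
    event_time: np.ndarray       # latent
    censor_time: np.ndarray      # latent
    observed_time: np.ndarray
    event: np.ndarray
    lesion_masks: list[np.ndarray]
    lesion_volume_vox: np.ndarray
    z_image: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "log_lambda": self.log_lambda.tolist(),
            "log_rho": self.log_rho.tolist(),
            "event_time": self.event_time.tolist(),
            "censor_time": np.where(
                np.isfinite(self.censor_time), self.censor_time, -1.0
            ).tolist(),
            "observed_time": self.observed_time.tolist(),
            "event": self.event.astype(int).tolist(),
            "lesion_volume_vox": self.lesion_volume_vox.tolist(),
            "z_image": self.z_image.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def _draw_covariates(rng: np.random.Generator, n: int) -> list[dict]:
    rows = []
    for _ in range(n):
        age = float(np.clip(rng.normal(55.0, 14.6), 18.0, 90.0))
        sex = "male" if rng.random() < 0.57 else "female"
        kps = int(rng.integers(3, 11) * 10)
        u = rng.random()
        if u < 0.70:
            histology, idh, codel = "glioblastoma", "wildtype", "non-codeleted"
            grade = "4"
        elif u < 0.85:
            histology, idh, codel = "astrocytoma", "mutated", "non-codeleted"
            grade = str(rng.choice(["2", "3", "4"]))
        else:
            histology, idh, codel = "oligodendroglioma", "mutated", "codeleted"
            grade = str(rng.choice(["2", "3"]))
        rows.append(
            {
                "age": age,
                "sex": sex,
                "kps": kps,
                "who_grade": grade,
                "histology": histology,
                "idh": idh,
                "codeletion_1p19q": codel,
                "mgmtp": "methylated" if rng.random() < 0.5 else "unmethylated",
                "eor": str(rng.choice(["gross total", "subtotal", "biopsy"],
                                      p=[0.6, 0.25, 0.15])),
                "radiotherapy": "received" if rng.random() < 0.7 else "not received",
                "chemotherapy": "received" if rng.random() < 0.6 else "not received",
            }
        )
    return rows


def ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def _make_volume(rng, shape, radii, noise_sd, generate: bool = True):
    """Zero-background 4-channel volume with an ellipsoidal lesion (smooth
    intensity falloff; rim enhancement on the T1C channel only) plus
    Gaussian noise.  With ``generate=False`` only the mask is built (the
    RNG stream is kept identical by drawing the same variates)."""
    shape = tuple(shape)
    center = [
        rng.uniform(r + 1, s - r - 1) if s - 2 * r - 2 > 0 else s / 2.0
        for s, r in zip(shape, radii)
    ]
    grids = np.indices(shape).astype(float)
    q = np.sqrt(sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii)))
    mask = q <= 1.0
    if not generate:
        rng.normal(0.0, 1.0, size=(4,) + shape)  # keep stream aligned
        return None, mask
    falloff = np.clip(1.0 - q, 0.0, 1.0) ** 2
    rim = np.exp(-(((q - 1.0) / 0.25) ** 2))  # bright shell at the lesion edge
    vol = np.zeros((4,) + shape)
    base = (0.6, 0.8, 1.0, 0.9)  # per-channel lesion contrast
    for c in range(4):
        vol[c] = base[c] * falloff
    vol[1] += 0.8 * rim  # contrast enhancement on T1C only
    vol += noise_sd * rng.normal(0.0, 1.0, size=vol.shape)
    return vol, mask


def _censoring_rate(times: np.ndarray, rate: float) -> float:
    return float(np.mean(1.0 - np.exp(-rate * times)))


def solve_censoring_rate(times: np.ndarray, target: float,
                         tol: float = 1e-10) -> float:
    """Bisection for the exponential censoring rate c with
    mean_i P(C < t_i) = target."""
    if target <= 0:
        return 0.0
    lo, hi = 0.0, 1.0
    while _censoring_rate(times, hi) < target:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("censoring target unattainable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _censoring_rate(times, mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimulationConfig):
    """Generate (records, truth, volumes).

    ``records`` are :class:`PatientRecord` with MAR missingness applied;
    ``truth`` holds the latent AFT parameters and outcomes; ``volumes`` is a
    list of (4, X, Y, Z) arrays aligned with the records.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    covs = _draw_covariates(rng, n)

    # imaging: lesion volumes drive z
    volumes, masks, vox_counts = [], [], []
    r_lo, r_hi = config.lesion_radius_range_vox
    for _ in range(n):
        radii = rng.uniform(r_lo, r_hi, size=3)
        radii[2] = max(1.0, radii[2] * config.volume_shape[2] / config.volume_shape[0])
        vol, mask = _make_volume(rng, config.volume_shape, radii,
                                 config.noise_sd, config.generate_volumes)
        volumes.append(vol)
        masks.append(mask)
        vox_counts.append(int(mask.sum()))
    vox_counts = np.asarray(vox_counts, float)
    logv = np.log(np.maximum(vox_counts, 1.0))
    sd = logv.std()
    z = (logv - logv.mean()) / sd if sd > 0 else np.zeros(n)

    # linear predictor
    coefs = dict(config.coef_log_lambda)
    intercept = coefs.pop("intercept", float(np.log(24.0)))
    log_lambda = np.full(n, intercept)
    for var, beta in coefs.items():
        if var not in _DESIGN:
            raise ValueError(f"unknown coefficient variable {var!r}")
        log_lambda += beta * np.array([_DESIGN[var](c) for c in covs])
    log_lambda = log_lambda + config.image_effect * z
    rho = np.exp(config.log_rho_true)

    # Weibull inverse-CDF event times
    u = np.clip(rng.uniform(size=n), 1e-12, 1 - 1e-12)
    event_time = np.exp(log_lambda) * (-np.log(u)) ** (1.0 / rho)
    event_time = np.maximum(event_time, 1e-3)

    # censoring calibrated to the target fraction
    if config.censoring_rate_target > 0:
        c_rate = solve_censoring_rate(event_time, config.censoring_rate_target)
        censor_time = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    # MAR missingness: probability depends on always-generated covariates
    # (sex, or age for sex itself), never on the outcome
    male = np.array([1.0 if c["sex"] == "male" else 0.0 for c in covs])
    age_hi = np.array([1.0 if c["age"] > 55 else 0.0 for c in covs])
    miss = {v: np.zeros(n, bool) for v in config.missing_rate}
    for var, rate in config.missing_rate.items():
        driver = age_hi if var == "sex" else male
        centered = driver - driver.mean()
        p = np.clip(rate * (1.0 + config.mar_strength * 2.0 * centered), 0.0, 0.95)
        miss[var] = rng.uniform(size=n) < p

    records = []
    for i, c in enumerate(covs):
        kwargs = dict(c)
        for var, m in miss.items():
            if m[i]:
                kwargs[var] = None
        records.append(
            PatientRecord(
                subject_id=f"S{i:04d}",
                os_months=float(observed[i]),
                event=int(event[i]),
                **{k: (str(v) if k == "who_grade" and v is not None else v)
                   for k, v in kwargs.items()},
            )
        )

    truth = GroundTruth(
        log_lambda=log_lambda,
        log_rho=np.full(n, config.log_rho_true),
        event_time=event_time,
        censor_time=censor_time,
        observed_time=observed,
        event=event,
        lesion_masks=masks,
        lesion_volume_vox=vox_counts,
        z_image=z,
    )
    return records, truth, volumes


def oracle_c_index(truth: GroundTruth) -> float:
    """Concordance of the TRUE risk (negative true median survival time)
    against the observed outcomes — the achievable ceiling for any model."""
    if len(truth.observed_time) < 2:
        raise ValueError("need at least 2 subjects")
    lam = np.exp(truth.log_lambda)
    rho = np.exp(truth.log_rho)
    true_median = lam * np.log(2.0) ** (1.0 / rho)
    return c_index(-true_median, truth.observed_time, truth.event)


def write_cohort_assets(records, truth, volumes, out_dir,
                        spacing=(1.0, 1.0, 4.0)) -> None:
    """Write cohort TSV, per-subject 4D NIfTI volumes + lesion masks, and a
    ground-truth JSON sidecar."""
    from dataclasses import replace as _replace

    from .tabular import write_cohort
    from .volumes import VolumeStack, save_stack

    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    linked = []
    for rec, vol, mask in zip(records, volumes, truth.lesion_masks):
        vpath = out / "volumes" / f"{rec.subject_id}.nii"
        mpath = out / "volumes" / f"{rec.subject_id}_mask.nii"
        save_stack(VolumeStack(vol, spacing, mask=mask.astype(np.uint8)),
                   vpath, mpath)
        linked.append(_replace(rec, volume_ref=str(vpath.relative_to(out))))
    write_cohort(linked, out / "cohort.tsv")
    truth.to_json(out / "ground_truth.json")
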