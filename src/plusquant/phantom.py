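"""Synthetic fundus phantoms with analytically known morphometry.

The generator emulates the posterior-pole geometry the pipeline
measures: a bright optic disc with vessels radiating outward, each
centerline a sine-perturbed ray

    P(t) = c + (r_d + t) u + A sin(2 pi t / lambda + phi) n,

where u is the radial direction and n its normal.  The parametric form
gives exact derivatives, so each curve carries an analytic curvature
profile and an SDC tortuosity computed by high-resolution quadrature —
ground truth for the morphometry estimators.  Vessels are rendered with
an anti-aliased width profile onto a background with radial vignetting
and Gaussian noise; the binary truth mask is the anti-aliased canvas
thresholded at 0.5.

A simulated expert panel grades images generated from a latent severity
theta in [1, 5]: severity raises sinusoidal amplitude, vessel width and
vessel count (dilation, tortuosity, density), and each simulated expert
applies noisy personal cut-points to theta — the mechanism behind
inter-expert disagreement on ordinal Plus grades.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import OpticDiscAnnotation, vascularized_region, vessel_density, RegionMask
from .grading import GradeTable
from .preprocess import RawImage

# How latent severity theta maps onto generator parameters (per unit of
# theta above 1): relative amplitude gain, relative width gain, extra
# vessels, extra branching probability.
SEVERITY_COEFFS = {
    "amplitude_gain": 0.55,
    "width_gain": 0.12,
    "vessels_per_level": 0.75,
    "branch_prob_per_level": 0.1,
}


@dataclass
class PhantomSpec:
    image_shape: tuple = (600, 800)
    disc_center: tuple = (300.0, 400.0)
    disc_diameter_px: float = 60.0
    n_main_vessels: int = 6
    branch_prob: float = 0.3
    sine_amplitude_px: float = 2.5
    sine_wavelength_px: float = 60.0
    base_width_px: float = 6.0
    width_decay: float = 0.0005  # fractional width loss per px of arc
    vessel_contrast: float = 0.55
    vignette_strength: float = 0.35
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.sine_amplitude_px < 0:
            raise ValueError("amplitude must be >= 0")
        if self.base_width_px < 2:
            raise ValueError("base width must be >= 2 px")
        if not 0 < self.vessel_contrast < 1:
            raise ValueError("contrast must be in (0, 1)")

    @property
    def disc(self) -> OpticDiscAnnotation:
        return OpticDiscAnnotation(center=self.disc_center, diameter_px=self.disc_diameter_px)


@dataclass
class SineVesselCurve:
    """One generating centerline: sine-perturbed ray with a width profile."""

    origin: tuple  # ray origin (row, col) at t = 0
    angle: float  # radians, image coords (row down)
    amplitude: float
    wavelength: float
    phase: float
    t_max: float
    width0: float
    width_decay: float

    def _uv(self):
        u = np.array([np.sin(self.angle), np.cos(self.angle)])  # (drow, dcol)
        n = np.array([u[1], -u[0]])
        return u, n

    def point(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        u, n = self._uv()
        omega = 2 * np.pi / self.wavelength
        wig = self.amplitude * np.sin(omega * t + self.phase)
        return np.asarray(self.origin) + t[..., None] * u + wig[..., None] * n

    def width(self, t: np.ndarray) -> np.ndarray:
        return np.maximum(2.0, self.width0 * (1.0 - self.width_decay * np.asarray(t)))

    def curvature(self, t: np.ndarray) -> np.ndarray:
        """Analytic signed curvature of the parametric curve."""
        t = np.asarray(t, dtype=float)
        u, n = self._uv()
        omega = 2 * np.pi / self.wavelength
        c1 = self.amplitude * omega * np.cos(omega * t + self.phase)
        c2 = -self.amplitude * omega**2 * np.sin(omega * t + self.phase)
        # derivatives in (x, y) = (col, row) convention used by curvature_profile
        xp = u[1] + c1 * n[1]
        yp = u[0] + c1 * n[0]
        xpp = c2 * n[1]
        ypp = c2 * n[0]
        return (xp * ypp - yp * xpp) / (xp**2 + yp**2) ** 1.5

    def speed(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        omega = 2 * np.pi / self.wavelength
        c1 = self.amplitude * omega * np.cos(omega * t + self.phase)
        return np.sqrt(1.0 + c1**2)

    def arc_length(self, n_quad: int = 4096) -> float:
        t = np.linspace(0.0, self.t_max, n_quad)
        return float(np.trapezoid(self.speed(t), t))

    def sdc_tortuosity(self, n_quad: int = 8192) -> float:
        """tau by high-resolution quadrature of (dkappa/ds)^2."""
        t = np.linspace(0.0, self.t_max, n_quad)
        kappa = self.curvature(t)
        sp = self.speed(t)
        dk_dt = np.gradient(kappa, t)
        dk_ds = dk_dt / sp
        integrand = dk_ds**2 * sp  # (dk/ds)^2 ds = (dk/ds)^2 s'(t) dt
        length = float(np.trapezoid(sp, t))
        return float(np.trapezoid(integrand, t) / length)


@dataclass
class PhantomTruth:
    mask: np.ndarray
    curves: list  # SineVesselCurve
    tortuosities: list  # analytic tau per curve
    widths: list  # width0 per curve
    stencil: np.ndarray  # vascularized-region ground truth
    true_density: float
    theta: float
    disc: OpticDiscAnnotation


@dataclass
class SimulatedPanel:
    n_experts: int = 4
    cut_points: np.ndarray | None = None  # (n_experts, 4) ascending
    noise_sd: np.ndarray | None = None  # per expert
    seed: int = 0

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        if self.cut_points is None:
            canonical = np.array([1.5, 2.5, 3.5, 4.5])
            jitter = rng.normal(0.0, 0.25, size=(self.n_experts, 4))
            cuts = np.sort(np.clip(canonical + jitter, 1.05, 4.95), axis=1)
            # enforce strict ascent
            for e in range(self.n_experts):
                for j in range(1, 4):
                    cuts[e, j] = max(cuts[e, j], cuts[e, j - 1] + 1e-3)
            self.cut_points = cuts
        else:
            self.cut_points = np.asarray(self.cut_points, dtype=float)
            if (np.diff(self.cut_points, axis=-1) <= 0).any():
                raise ValueError("cut points must be strictly ascending")
        if self.noise_sd is None:
            self.noise_sd = np.full(self.n_experts, 0.3)
        else:
            self.noise_sd = np.asarray(self.noise_sd, dtype=float)


# ---------------------------------------------------------------------------
# rendering


def _stamp_curve(canvas: np.ndarray, curve: SineVesselCurve, spacing: float = 0.25) -> None:
    """Draw an anti-aliased tube for `curve` into the soft canvas (max-blend)."""
    h, w = canvas.shape
    n_samp = max(2, int(np.ceil(curve.t_max / spacing)) + 1)
    t = np.linspace(0.0, curve.t_max, n_samp)
    pts = curve.point(t)
    radii = curve.width(t) / 2.0
    for (r, c), rad in zip(pts, radii):
        lo_r, hi_r = int(np.floor(r - rad - 1)), int(np.ceil(r + rad + 2))
        lo_c, hi_c = int(np.floor(c - rad - 1)), int(np.ceil(c + rad + 2))
        if hi_r < 0 or hi_c < 0 or lo_r >= h or lo_c >= w:
            continue
        lo_r, hi_r = max(0, lo_r), min(h, hi_r)
        lo_c, hi_c = max(0, lo_c), min(w, hi_c)
        rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        dist = np.hypot(rr - r, cc - c)
        soft = np.clip(rad + 0.5 - dist, 0.0, 1.0)
        window = canvas[lo_r:hi_r, lo_c:hi_c]
        np.maximum(window, soft, out=window)


def _make_curves(spec: PhantomSpec, rng: np.random.Generator) -> list:
    h, w = spec.image_shape
    r_d = spec.disc_diameter_px / 2.0
    curves = []
    base_angles = np.linspace(0.0, 2 * np.pi, spec.n_main_vessels, endpoint=False)
    for ang0 in base_angles:
        ang = ang0 + rng.uniform(-0.25, 0.25)
        u = np.array([np.sin(ang), np.cos(ang)])
        origin = np.asarray(spec.disc_center) + r_d * u
        # extend until the straight ray leaves the frame (with margin)
        t_max = _ray_exit_t(origin, u, (h, w), margin=4.0)
        if t_max < 30:
            continue
        amp = spec.sine_amplitude_px * rng.uniform(0.8, 1.2)
        curve = SineVesselCurve(
            origin=tuple(origin),
            angle=ang,
            amplitude=amp,
            wavelength=spec.sine_wavelength_px * rng.uniform(0.85, 1.15),
            phase=rng.uniform(0, 2 * np.pi),
            t_max=t_max,
            width0=spec.base_width_px * rng.uniform(0.85, 1.1),
            width_decay=spec.width_decay,
        )
        curves.append(curve)
        if rng.uniform() < spec.branch_prob:
            t_b = rng.uniform(0.3, 0.6) * t_max
            p_b = curve.point(np.array([t_b]))[0]
            ang_b = ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.35, 0.7)
            u_b = np.array([np.sin(ang_b), np.cos(ang_b)])
            t_max_b = min(_ray_exit_t(p_b, u_b, (h, w), margin=4.0), 0.7 * t_max)
            if t_max_b >= 30:
                curves.append(
                    SineVesselCurve(
                        origin=tuple(p_b),
                        angle=ang_b,
                        amplitude=0.6 * amp,
                        wavelength=spec.sine_wavelength_px * rng.uniform(0.85, 1.15),
                        phase=rng.uniform(0, 2 * np.pi),
                        t_max=t_max_b,
                        width0=0.6 * curve.width0,
                        width_decay=spec.width_decay,
                    )
                )
    if not curves:
        raise ValueError("no vessel fits inside the image; enlarge the frame")
    return curves


def _ray_exit_t(origin: np.ndarray, u: np.ndarray, shape: tuple, margin: float = 4.0) -> float:
    h, w = shape
    ts = []
    for coord, d, lim in ((origin[0], u[0], h), (origin[1], u[1], w)):
        if d > 1e-9:
            ts.append((lim - 1 - margin - coord) / d)
        elif d < -1e-9:
            ts.append((margin - coord) / d)
    return max(0.0, min(ts)) if ts else 0.0


def generate_phantom(spec: PhantomSpec) -> tuple:
    """Render one phantom; returns ``(RawImage, PhantomTruth)``.

    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    curves = _make_curves(spec, rng)
    soft = np.zeros((h, w), dtype=float)
    for curve in curves:
        _stamp_curve(soft, curve)
    mask = soft >= 0.5
    # disc interior carries no vessels in the truth mask
    rr, cc = np.mgrid[0:h, 0:w]
    disc_dist = np.hypot(rr - spec.disc_center[0], cc - spec.disc_center[1])
    r_d = spec.disc_diameter_px / 2.0
    mask &= disc_dist > r_d
    soft = np.where(disc_dist > r_d, soft, 0.0)

    background = 0.62
    img = background * (1.0 - spec.vessel_contrast * soft)
    img = np.where(disc_dist <= r_d, np.clip(img + 0.25, 0, 1), img)  # bright disc
    rmax = np.hypot(h / 2.0, w / 2.0)
    center_dist = np.hypot(rr - h / 2.0, cc - w / 2.0)
    vignette = 1.0 - spec.vignette_strength * (center_dist / rmax) ** 2
    img = img * vignette + rng.normal(0.0, spec.noise_sd, size=(h, w))
    img = np.clip(img, 0.0, 1.0)
    rgb = np.stack(
        [np.clip(img * 1.15, 0, 1), img, img * 0.45], axis=-1
    )
    raw = RawImage((np.round(rgb * 255)).astype(np.uint8), image_id=f"phantom_{spec.seed}")

    stencil = vascularized_region(mask).mask
    density = vessel_density(mask, RegionMask(stencil, "whole_vascularized"))
    truth = PhantomTruth(
        mask=mask,
        curves=curves,
        tortuosities=[c.sdc_tortuosity() for c in curves],
        widths=[c.width0 for c in curves],
        stencil=stencil,
        true_density=density,
        theta=1.0,
        disc=spec.disc,
    )
    return raw, truth


def severity_to_spec(theta: float, base: PhantomSpec) -> PhantomSpec:
    """Map a latent severity theta in [1, 5] onto generator parameters.

    theta = 1 returns the base spec unchanged; larger theta increases
    sinusoidal amplitude, vessel width and vessel count affinely with the
    coefficients in :data:`SEVERITY_COEFFS`.
    """
    if not 1.0 <= theta <= 5.0:
        raise ValueError("theta must lie in [1, 5]")
    excess = theta - 1.0
    c = SEVERITY_COEFFS
    return replace(
        base,
        sine_amplitude_px=base.sine_amplitude_px * (1 + c["amplitude_gain"] * excess),
        base_width_px=base.base_width_px * (1 + c["width_gain"] * excess),
        n_main_vessels=base.n_main_vessels + int(round(c["vessels_per_level"] * excess)),
        branch_prob=min(1.0, base.branch_prob + c["branch_prob_per_level"] * excess),
    )


def simulate_grades(theta_list, panel: SimulatedPanel, seed: int = 0,
                    image_ids: list | None = None) -> GradeTable:
    """Grade latent severities through each simulated expert's noisy cut-points."""
    theta = np.asarray(theta_list, dtype=float)
    rng = np.random.default_rng(seed)
    cols = {}
    for e in range(panel.n_experts):
        noisy = theta + rng.normal(0.0, panel.noise_sd[e], size=theta.shape)
        grades = 1 + (noisy[:, None] > panel.cut_points[e][None, :]).sum(axis=1)
        cols[f"E{e + 1}"] = np.clip(grades, 1, 5)
    ids = image_ids or [f"img_{i:04d}" for i in range(len(theta))]
    df = pd.DataFrame(cols, index=pd.Index(ids, name="image_id"))
    return GradeTable(df)


def generate_cohort(
    n: int,
    panel: SimulatedPanel | None = None,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    out_dir=None,
    render: bool = True,
) -> tuple:
    """Draw theta_i ~ U[1, 5], render phantoms and simulate the grade table.

    Returns ``(raws, truths, grade_table, thetas)``; with ``out_dir`` the
    bundle is written in the pipeline's input layout (images/, masks/,
    discs.csv, grades.csv, truth.json).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    panel = panel or SimulatedPanel(seed=seed + 1)
    base_spec = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    thetas = rng.uniform(1.0, 5.0, size=n)
    raws, truths = [], []
    ids = [f"img_{i:04d}" for i in range(n)]
    if render:
        for i, th in enumerate(thetas):
            spec_i = replace(severity_to_spec(float(th), base_spec), seed=int(seed * 100003 + i) % (2**31))
            raw, truth = generate_phantom(spec_i)
            raw.image_id = ids[i]
            truth.theta = float(th)
            raws.append(raw)
            truths.append(truth)
    table = simulate_grades(thetas, panel, seed=seed + 2, image_ids=ids)
    if out_dir is not None:
        _write_cohort(Path(out_dir), raws, truths, table, thetas, ids)
    return raws, truths, table, thetas


def _write_cohort(out: Path, raws, truths, table: GradeTable, thetas, ids) -> None:
    from PIL import Image

    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    disc_rows = []
    for raw, truth, iid in zip(raws, truths, ids):
        Image.fromarray(raw.pixels).save(out / "images" / f"{iid}.png")
        Image.fromarray((truth.mask * 255).astype(np.uint8)).save(out / "masks" / f"{iid}.png")
        disc_rows.append(
            {
                "image_id": iid,
                "center_row": truth.disc.center[0],
                "center_col": truth.disc.center[1],
                "diameter_px": truth.disc.diameter_px,
            }
        )
    pd.DataFrame(disc_rows).to_csv(out / "discs.csv", index=False)
    table.grades.to_csv(out / "grades.csv")
    meta = {
        iid: {"theta": float(th), "true_density": float(tr.true_density),
              "tortuosities": [float(t) for t in tr.tortuosities]}
        for iid, th, tr in zip(ids, thetas, truths)
    }
    (out / "truth.json").write_text(json.dumps(meta, indent=2))
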