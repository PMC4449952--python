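"""Seeded synthetic XA phantom with known respiratory and cardiac motion.

Clinical XA is not publicly shareable, so every pipeline stage is
exercised against this generator instead.  It emulates the scene content
of interventional coronary angiograms:

* a bright background (~200 on an 8-bit-like scale) with a smooth
  intensity gradient and low-frequency lung texture;
* a dark diaphragm region under a parabolic border whose vertical
  position oscillates quasi-sinusoidally at the breathing rate, with the
  border itself slightly darker than the interior (as the projected dome
  edge appears in fluoroscopy);
* a dark branching vessel tree and optional catheter, displaced at the
  cardiac rate plus a fraction of the breathing displacement;
* exponential contrast fade of the vessels after a configurable frame,
  emulating contrast-agent washout partway through every acquisition;
* additive Gaussian noise.

Lung texture shifts vertically with a fraction of the breathing
displacement, so sequences without a visible diaphragm still carry
respiratory intensity variation (as in patients whose diaphragm is
outside the field of view).

Everything is deterministic given the seed: the same seed reproduces the
sequence bit for bit, and a biplane pair shares its motion signals while
differing in scene geometry (mirrored vessel layout, independent
background, texture and noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .io import DiaphragmTrack, ROIRect, XASequence


@dataclass
class PhantomConfig:
    """All parameters of the synthetic scene and motion model.

    Defaults describe a typical 512x512 acquisition at 15 frames/s with
    0.216 mm pixels: tidal breathing of ~13 mm peak-to-peak diaphragm
    excursion (30 px amplitude) at 0.25 Hz with 15% breath-to-breath
    amplitude variability, cardiac vessel displacement of ~3 mm amplitude
    (14 px) at 1.2 Hz, projected vessel calibers of ~3 mm (14 px) and a
    ~2 mm catheter, contrast fading from frame 60, and noise sigma 4.
    """

    height: int = 512
    width: int = 512
    n_frames: int = 120
    frame_rate_hz: float = 15.0
    pixel_spacing_mm: float = 0.216

    breathing_amplitude_px: float = 30.0
    breathing_freq_hz: float = 0.25
    breathing_phase: float = 0.0
    breathing_drift_px_per_s: float = 0.0
    breathing_amplitude_jitter: float = 0.15

    cardiac_amplitude_px: float = 14.0
    cardiac_freq_hz: float = 1.2
    cardiac_phase: float = 0.0

    diaphragm: bool = True
    diaphragm_apex_x: float = 320.0
    diaphragm_apex_y: float = 330.0
    diaphragm_curvature: float = 0.0008
    diaphragm_depth: float = 80.0
    border_depth: float = 50.0
    border_sigma_px: float = 1.5

    n_vessel_branches: int = 4
    vessel_width_px: float = 14.0
    vessel_contrast: float = 90.0
    vessel_breathing_coupling: float = 0.7

    catheter: bool = True
    catheter_width_px: float = 9.0
    catheter_contrast: float = 70.0

    fade_start_frame: int = 60
    fade_tau_s: float = 1.0

    texture_breathing_coupling: float = 0.3
    texture_amplitude: float = 12.0
    background_level: float = 200.0
    noise_sigma: float = 4.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.breathing_freq_hz <= 0 or self.cardiac_freq_hz <= 0:
            raise ValueError("motion frequencies must be positive")
        if self.breathing_freq_hz >= self.cardiac_freq_hz:
            raise ValueError("breathing must be slower than cardiac motion")
        if self.breathing_amplitude_px < 0 or self.cardiac_amplitude_px < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.vessel_width_px < 1 or self.catheter_width_px < 1:
            raise ValueError("structure widths must be >= 1 px")
        duration = self.n_frames / self.frame_rate_hz
        reach = (
            self.breathing_amplitude_px
            * (1.0 + self.breathing_amplitude_jitter)
            + abs(self.breathing_drift_px_per_s) * duration
        )
        margin = 6.0 * self.border_sigma_px
        if self.diaphragm and (
            self.diaphragm_apex_y - reach - margin < 0
            or self.diaphragm_apex_y + reach + margin >= self.height
        ):
            raise ValueError(
                "diaphragm outside frame at motion extremes; reduce the "
                "breathing amplitude or move the apex"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomScene:
    """A generated phantom: sequence plus all ground truth and geometry."""

    sequence: XASequence
    truth: DiaphragmTrack
    cardiac_signal: np.ndarray
    config: PhantomConfig
    roi: ROIRect
    resp: np.ndarray
    base_border: np.ndarray  # rest border y per column (W,)
    vessel_polylines: list = field(default_factory=list)
    catheter_polyline: np.ndarray | None = None

    def swept_band_mask(
        self, factor: int = 1, margin_px: float = 0.0
    ) -> np.ndarray:
        """Boolean mask of the band swept by the diaphragm border.

        Computed per column from the rest border and the realized
        breathing excursion, dilated by ``margin_px`` (original-resolution
        pixels), then reduced to the downsampled grid by block-max.
        """
        h, w = self.config.height, self.config.width
        lo = self.base_border + self.resp.min() - margin_px
        hi = self.base_border + self.resp.max() + margin_px
        ys = np.arange(h)[:, None]
        mask = (ys >= lo[None, :]) & (ys <= hi[None, :])
        return _block_max(mask, factor)

    def vessel_centerline_mask(self, factor: int = 1) -> np.ndarray:
        """Boolean mask of rest-position vessel centerlines on the
        (optionally downsampled) grid."""
        h, w = self.config.height, self.config.width
        mask = np.zeros((h, w), dtype=bool)
        lines = list(self.vessel_polylines)
        if self.catheter_polyline is not None:
            lines.append(self.catheter_polyline)
        for poly in lines:
            for (x0, y0), (x1, y1) in zip(poly[:-1], poly[1:]):
                n = int(np.hypot(x1 - x0, y1 - y0)) * 2 + 2
                xs = np.clip(np.linspace(x0, x1, n), 0, w - 1).astype(int)
                ys = np.clip(np.linspace(y0, y1, n), 0, h - 1).astype(int)
                mask[ys, xs] = True
        return _block_max(mask, factor)


def _block_max(mask: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return mask
    h, w = mask.shape
    pad_h = (-h) % factor
    pad_w = (-w) % factor
    if pad_h or pad_w:
        mask = np.pad(mask, ((0, pad_h), (0, pad_w)), mode="edge")
        h, w = mask.shape
    return mask.reshape(h // factor, factor, w // factor, factor).max(
        axis=(1, 3)
    )


# ---------------------------------------------------------------------------
# motion and scene construction
# ---------------------------------------------------------------------------

def _motion_signals(cfg: PhantomConfig):
    """Deterministic breathing / cardiac / fade signals shared by planes."""
    t = np.arange(cfg.n_frames) / cfg.frame_rate_hz
    amp = np.full(cfg.n_frames, cfg.breathing_amplitude_px)
    if cfg.breathing_amplitude_jitter > 0:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
        jitter_phase = rng.uniform(0, 2 * np.pi)
        amp = amp * (
            1.0
            + cfg.breathing_amplitude_jitter
            * np.sin(2 * np.pi * 0.05 * t + jitter_phase)
        )
    resp = (
        amp * np.sin(2 * np.pi * cfg.breathing_freq_hz * t + cfg.breathing_phase)
        + cfg.breathing_drift_px_per_s * t
    )
    card = cfg.cardiac_amplitude_px * np.sin(
        2 * np.pi * cfg.cardiac_freq_hz * t + cfg.cardiac_phase
    )
    fade = np.ones(cfg.n_frames)
    if cfg.fade_start_frame < cfg.n_frames:
        tau_frames = max(cfg.fade_tau_s * cfg.frame_rate_hz, 1e-6)
        k = np.arange(cfg.n_frames) - cfg.fade_start_frame
        fade = np.where(k > 0, np.exp(-k / tau_frames), 1.0)
    return resp, card, fade


def _smooth_texture(rng, height, width, amplitude, cell=32):
    coarse = rng.normal(
        size=(height // cell + 4, width // cell + 4)
    )
    tex = ndimage.zoom(coarse, cell, order=3)[:height, :width]
    return amplitude * tex / max(np.abs(tex).max(), 1e-9)


def _make_vessel_tree(rng, cfg: PhantomConfig, mirror: bool):
    """Random branching polylines kept above the diaphragm sweep zone."""
    w, h = cfg.width, cfg.height
    y_limit = (
        cfg.diaphragm_apex_y
        - cfg.breathing_amplitude_px
        - 45.0
    )
    x_lo, x_hi = 0.05 * w, 0.50 * w

    def _clamp(pt):
        return (
            float(np.clip(pt[0], x_lo, x_hi)),
            float(np.clip(pt[1], 5.0, y_limit)),
        )

    trunk = [(_clamp((rng.uniform(0.18, 0.30) * w, 8.0)))]
    angle = np.pi / 2 + rng.uniform(-0.2, 0.2)  # mostly downward
    step = h / 9.0
    for _ in range(6):
        angle += rng.uniform(-0.4, 0.4)
        x = trunk[-1][0] + step * np.cos(angle)
        y = trunk[-1][1] + step * np.sin(angle)
        trunk.append(_clamp((x, y)))
    polylines = [np.asarray(trunk)]

    for _ in range(max(cfg.n_vessel_branches - 1, 0)):
        start_idx = rng.integers(1, len(trunk) - 1)
        pts = [trunk[start_idx]]
        angle = np.pi / 2 + rng.uniform(-1.0, 1.0)
        for _ in range(4):
            angle += rng.uniform(-0.5, 0.5)
            x = pts[-1][0] + 0.8 * step * np.cos(angle)
            y = pts[-1][1] + 0.8 * step * np.sin(angle)
            pts.append(_clamp((x, y)))
        polylines.append(np.asarray(pts))

    catheter = None
    if cfg.catheter:
        xs = np.linspace(0.10 * w, 0.22 * w, 8) + 6.0 * np.sin(
            np.linspace(0, 2.2, 8) + rng.uniform(0, 1)
        )
        ys = np.linspace(0.0, min(0.55 * h, y_limit), 8)
        catheter = np.column_stack([np.clip(xs, x_lo, x_hi), ys])

    if mirror:
        polylines = [
            np.column_stack([w - 1 - p[:, 0], p[:, 1]]) for p in polylines
        ]
        if catheter is not None:
            catheter = np.column_stack(
                [w - 1 - catheter[:, 0], catheter[:, 1]]
            )
    if cfg.n_vessel_branches == 0:
        polylines = []
    return polylines, catheter


def _draw_tube_max(layer, p0, p1, sigma, depth):
    """Accumulate a Gaussian-profile dark tube segment into a max-layer."""
    h, w = layer.shape
    reach = 3.0 * sigma + 1.0
    x_lo = int(max(np.floor(min(p0[0], p1[0]) - reach), 0))
    x_hi = int(min(np.ceil(max(p0[0], p1[0]) + reach), w - 1))
    y_lo = int(max(np.floor(min(p0[1], p1[1]) - reach), 0))
    y_hi = int(min(np.ceil(max(p0[1], p1[1]) + reach), h - 1))
    if x_hi < x_lo or y_hi < y_lo:
        return
    xs = np.arange(x_lo, x_hi + 1, dtype=np.float64)
    ys = np.arange(y_lo, y_hi + 1, dtype=np.float64)
    px, py = np.meshgrid(xs - p0[0], ys - p0[1])
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    seg2 = dx * dx + dy * dy
    if seg2 < 1e-12:
        d2 = px * px + py * py
    else:
        t = np.clip((px * dx + py * dy) / seg2, 0.0, 1.0)
        d2 = (px - t * dx) ** 2 + (py - t * dy) ** 2
    profile = depth * np.exp(-d2 / (2.0 * sigma * sigma))
    region = layer[y_lo : y_hi + 1, x_lo : x_hi + 1]
    np.maximum(region, profile, out=region)


def _render_plane(
    cfg: PhantomConfig,
    resp: np.ndarray,
    card: np.ndarray,
    fade: np.ndarray,
    scene_rng: np.random.Generator,
    mirror: bool,
    plane_id: str,
) -> PhantomScene:
    h, w = cfg.height, cfg.width
    n = cfg.n_frames

    # static scene elements
    gdir = scene_rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    background = cfg.background_level + 10.0 * (
        np.cos(gdir) * (xx / w - 0.5) + np.sin(gdir) * (yy / h - 0.5)
    )

    max_shift = int(
        np.ceil(cfg.texture_breathing_coupling * (np.abs(resp).max() + 1))
    ) + 2
    texture = _smooth_texture(
        scene_rng, h + 2 * max_shift, w, cfg.texture_amplitude
    )

    polylines, catheter = _make_vessel_tree(scene_rng, cfg, mirror)

    apex_x = w - 1 - cfg.diaphragm_apex_x if mirror else cfg.diaphragm_apex_x
    cols = np.arange(w, dtype=np.float64)
    base_border = (
        cfg.diaphragm_apex_y
        + cfg.diaphragm_curvature * (cols - apex_x) ** 2
    )

    ys_col = np.arange(h, dtype=np.float64)[:, None]
    frames = np.empty((n, h, w), dtype=np.float32)
    row_idx = np.arange(h, dtype=np.float64)

    for i in range(n):
        # lung texture rides on a fraction of the breathing displacement
        shift = cfg.texture_breathing_coupling * resp[i]
        pos = row_idx + max_shift - shift
        lo = np.floor(pos).astype(int)
        frac = (pos - lo)[:, None]
        img = background + texture[lo] * (1.0 - frac) + texture[lo + 1] * frac

        if cfg.diaphragm:
            border = base_border[None, :] + resp[i]
            z = (ys_col - border) / 2.0
            img -= cfg.diaphragm_depth * expit(z)
            img -= cfg.border_depth * np.exp(
                -((ys_col - border) ** 2)
                / (2.0 * cfg.border_sigma_px**2)
            )

        layer = np.zeros((h, w), dtype=np.float64)
        vdx = 0.4 * card[i]
        vdy = card[i] + cfg.vessel_breathing_coupling * resp[i]
        depth_i = cfg.vessel_contrast * fade[i]
        if depth_i > 0.5:
            for poly in polylines:
                pts = poly + np.array([vdx, vdy])
                for p0, p1 in zip(pts[:-1], pts[1:]):
                    _draw_tube_max(
                        layer, p0, p1, cfg.vessel_width_px / 2.0, depth_i
                    )
        if catheter is not None:
            # the catheter stays: it is a device, not contrast agent
            pts = catheter + np.array(
                [0.3 * card[i], 0.5 * card[i] + 0.6 * resp[i]]
            )
            for p0, p1 in zip(pts[:-1], pts[1:]):
                _draw_tube_max(
                    layer,
                    p0,
                    p1,
                    cfg.catheter_width_px / 2.0,
                    cfg.catheter_contrast,
                )
        img -= layer

        img += scene_rng.normal(0.0, cfg.noise_sigma, size=(h, w))
        frames[i] = np.clip(img, 0.0, 255.0)

    seq = XASequence(
        frames=frames,
        pixel_spacing_mm=cfg.pixel_spacing_mm,
        frame_rate_hz=cfg.frame_rate_hz,
        plane_id=plane_id,
        name=f"phantom-seed{cfg.seed}-{plane_id}",
    )

    reach = np.abs(resp).max()
    roi_half_h = min(reach + 20.0, cfg.diaphragm_apex_y - 1, h - cfg.diaphragm_apex_y - 2)
    roi = ROIRect(
        x0=int(np.clip(apex_x - 24, 0, w - 48)),
        y0=int(cfg.diaphragm_apex_y - roi_half_h),
        width=48,
        height=int(2 * roi_half_h),
    )
    truth = DiaphragmTrack(
        positions=cfg.diaphragm_apex_y + resp,
        roi=roi,
        source="phantom_truth",
    )
    return PhantomScene(
        sequence=seq,
        truth=truth,
        cardiac_signal=card.copy(),
        config=cfg,
        roi=roi,
        resp=resp.copy(),
        base_border=base_border,
        vessel_polylines=polylines,
        catheter_polyline=catheter,
    )


def generate(cfg: PhantomConfig) -> PhantomScene:
    """Generate one synthetic XA sequence with ground-truth motion.

    Returns a :class:`PhantomScene` bundling the sequence, the per-frame
    diaphragm truth track, the cardiac signal and the scene geometry.
    Fully deterministic given ``cfg.seed``.
    """
    resp, card, fade = _motion_signals(cfg)
    scene_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    return _render_plane(cfg, resp, card, fade, scene_rng, False, "A")


def generate_biplane(cfg: PhantomConfig) -> tuple[PhantomScene, PhantomScene]:
    """Generate a time-synchronized biplane pair.

    Both planes share the same motion signals and truth track (the same
    object) but have mirrored vessel layout, different background
    gradient/texture and independent noise.
    """
    resp, card, fade = _motion_signals(cfg)
    rng_a = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    rng_b = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    scene_a = _render_plane(cfg, resp, card, fade, rng_a, False, "A")
    scene_b = _render_plane(cfg, resp, card, fade, rng_b, True, "B")
    scene_b.truth = scene_a.truth  # shared ground truth object
    return scene_a, scene_b
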