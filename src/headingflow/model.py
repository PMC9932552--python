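"""Simplified Competitive Dynamics model of MT/MSTd heading estimation.

Processing stages per optic-flow frame:

1. **MT pooling** — the horizontal and vertical flow components are each
   convolved with a unit-sum 2-D Gaussian (SD ``sigma_mt``, truncated at
   radius ``r_mt``), modelling spatial motion pooling by MT units without
   suppressive surrounds.
2. **MSTd template match** — the pooled field is dotted against a bank of
   radial-expansion templates, one per focus-of-expansion position sampled
   at every pixel column along the horizontal midline.  Template vectors are
   unit vectors away from the FoE weighted by inverse distance to the FoE;
   negative matches (e.g., contraction) are rectified to zero.
3. **Cross-heading smoothing** — the activation profile over templates is
   smoothed with a unit-sum 1-D Gaussian (SD ``sigma_mst``, radius
   ``r_mst``), edge kernels renormalized.
4. **Recurrent competition** — the smoothed drive is temporally averaged
   (exponential moving average, constant ``c``) and fed to a recurrent
   shunting on-center/off-surround field

       dx_i/dt = -A x_i + (B - x_i) (I_i + f(x_i)) - x_i sum_{j!=i} f(x_j)

   with passive decay ``A``, excitatory upper bound ``B`` and a
   faster-than-linear signal function ``f`` that contrast-enhances winners.
5. **Population-vector decode** — the heading estimate is the
   activation-weighted mean of the templates' preferred headings,
   i* = sum_i x_i h_i / sum_i x_i.

On blackout frames the drive is all-zero and the state evolves on the
recurrent dynamics alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .flow import FlowSample, SceneConfig

__all__ = [
    "ModelParams",
    "TemplateBank",
    "MSTdState",
    "HeadingEstimate",
    "TrialResult",
    "mt_pool",
    "build_templates",
    "template_match",
    "smooth_activations",
    "step_dynamics",
    "decode_heading",
    "run_trial",
]


class UndefinedEstimateError(RuntimeError):
    """Population-vector decode attempted on an all-zero activation state."""


def squared(x: np.ndarray) -> np.ndarray:
    """Default faster-than-linear signal function, f(x) = x^2."""
    return x * x


@dataclass(frozen=True)
class ModelParams:
    """Model parameters; defaults are the reference simulation values.

    Radii and SDs are in pixels of the 128x128 flow grid.  ``a_decay`` is
    the passive decay rate, ``b_ceiling`` the shunting excitatory upper
    bound, ``c_avg`` the exponential-moving-average constant applied to the
    drive.  ``drive_gain`` rescales raw template activations so peak drive
    on a full-field expansion frame is of order one; ``None`` uses the
    reference gain computed when the template bank is built.  Integration
    uses ``substeps_per_frame`` steps of size ``dt`` (frame fractions) per
    stimulus frame.

    ``drive_scale`` multiplies the bank's reference gain and sets the
    operating point of the shunting field: the default places the model in
    the winner-dominated evidence-accumulation regime, just below the
    transition where the instantaneous input overrides the recurrent
    history (fixed once by the drive calibration in
    :mod:`headingflow.experiment`).
    """

    r_mt: float = 6.0
    sigma_mt: float = 9.51
    r_mst: float = 19.0
    sigma_mst: float = 10.08
    a_decay: float = 0.81
    b_ceiling: float = 146.0
    c_avg: float = 0.7
    dt: float = 0.1
    substeps_per_frame: int = 10
    drive_scale: float = 2000.0
    drive_gain: float | None = None
    signal_fn: Callable[[np.ndarray], np.ndarray] = squared

    def __post_init__(self) -> None:
        if not (0.0 <= self.c_avg <= 1.0):
            raise ValueError("c_avg must lie in [0, 1]")
        if self.a_decay <= 0 or self.b_ceiling <= 0:
            raise ValueError("a_decay and b_ceiling must be positive")
        if self.dt <= 0 or self.substeps_per_frame < 1:
            raise ValueError("invalid integration settings")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        """Build from a mapping using the conventional short names
        (rMT, sigmaMT, rMST, sigmaMST, A, B, c) or the field names."""
        alias = {
            "rMT": "r_mt",
            "sigmaMT": "sigma_mt",
            "rMST": "r_mst",
            "sigmaMST": "sigma_mst",
            "A": "a_decay",
            "B": "b_ceiling",
            "c": "c_avg",
        }
        return cls(**{alias.get(k, k): v for k, v in d.items()})

    def to_dict(self) -> dict:
        return {
            "rMT": self.r_mt,
            "sigmaMT": self.sigma_mt,
            "rMST": self.r_mst,
            "sigmaMST": self.sigma_mst,
            "A": self.a_decay,
            "B": self.b_ceiling,
            "c": self.c_avg,
            "dt": self.dt,
            "substeps_per_frame": self.substeps_per_frame,
        }


def _gaussian_kernel_2d(sigma: float, radius: int) -> np.ndarray:
    """Unit-sum 2-D Gaussian truncated at the given radius (circular support)."""
    ax = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    k[xx**2 + yy**2 > radius**2] = 0.0
    return k / k.sum()


def _gaussian_kernel_1d(sigma: float, radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    k = np.exp(-(ax**2) / (2.0 * sigma**2))
    return k / k.sum()


def mt_pool(flow_frame: np.ndarray, params: ModelParams) -> np.ndarray:
    """Convolve each flow component with the truncated MT Gaussian.

    Zero padding at the image border; the kernel is unit-sum so uniform
    fields pass through unchanged away from the border.
    """
    kernel = _gaussian_kernel_2d(params.sigma_mt, int(round(params.r_mt)))
    out = np.empty_like(flow_frame)
    for comp in range(flow_frame.shape[-1]):
        out[..., comp] = ndimage.convolve(
            flow_frame[..., comp], kernel, mode="constant", cval=0.0
        )
    return out


@dataclass
class TemplateBank:
    """Radial-expansion heading templates, one per pixel column.

    ``templates`` has shape (n_templates, H, W, 2); template k's FoE sits at
    column k on the horizontal midline and its preferred heading is
    ``headings[k]`` under the linear angle<->pixel map.  ``reference_gain``
    rescales raw matches so the peak activation to a unit-magnitude
    full-field expansion about the central FoE equals one.
    """

    templates: np.ndarray
    headings: np.ndarray
    reference_gain: float

    @property
    def n_templates(self) -> int:
        return self.templates.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """(n_templates, H*W*2) view for fast matching."""
        m = getattr(self, "_matrix", None)
        if m is None:
            m = self.templates.reshape(self.n_templates, -1)
            object.__setattr__(self, "_matrix", m)
        return m


def _radial_field(res: int, foe_row: float, foe_col: float, weighted: bool) -> np.ndarray:
    """Unit radial expansion field about a FoE, optionally 1/d weighted.

    Vectors point away from the FoE; the vertical component is stored
    positive-upward to match the flow convention (row index grows
    downward).  A pixel coincident with the FoE carries a zero vector.
    """
    rows, cols = np.meshgrid(np.arange(res), np.arange(res), indexing="ij")
    dx = cols - foe_col
    dy = foe_row - rows  # upward-positive
    d = np.hypot(dx, dy)
    safe = np.where(d > 0, d, 1.0)
    fld = np.stack([dx / safe, dy / safe], axis=-1)
    fld[d == 0] = 0.0
    if weighted:
        w = np.minimum(1.0, 1.0 / safe)
        w[d == 0] = 0.0
        fld *= w[..., None]
    return fld


def build_templates(
    resolution: int = 128, config: SceneConfig | None = None
) -> TemplateBank:
    """Build one template per pixel column along the horizontal midline."""
    config = config or SceneConfig(resolution=resolution)
    if resolution <= 1:
        raise ValueError("resolution must exceed 1")
    mid = (resolution - 1) / 2.0
    templates = np.empty((resolution, resolution, resolution, 2))
    for k in range(resolution):
        templates[k] = _radial_field(resolution, mid, float(k), weighted=True)
    headings = config.azimuth_of_col(np.arange(resolution))
    # gain: unit-magnitude expansion about the image center drives the
    # best-matching template to activation 1
    center = _radial_field(resolution, mid, mid, weighted=False)
    raw = templates.reshape(resolution, -1) @ center.ravel()
    bank = TemplateBank(
        templates=templates, headings=headings, reference_gain=1.0 / raw.max()
    )
    return bank


def template_match(
    pooled_frame: np.ndarray, bank: TemplateBank, params: ModelParams | None = None
) -> np.ndarray:
    """Dot each template against the pooled flow; rectify at zero.

    Returns the n_templates raw activation vector scaled by the drive gain:
    ``params.drive_gain`` if given, else the bank's reference gain times
    ``params.drive_scale``.
    """
    if params is None:
        gain = bank.reference_gain
    elif params.drive_gain is not None:
        gain = params.drive_gain
    else:
        gain = bank.reference_gain * params.drive_scale
    raw = bank.matrix @ pooled_frame.ravel()
    return np.maximum(raw, 0.0) * gain


def smooth_activations(raw: np.ndarray, params: ModelParams) -> np.ndarray:
    """1-D Gaussian smoothing across templates, renormalized at the edges."""
    kernel = _gaussian_kernel_1d(params.sigma_mst, int(round(params.r_mst)))
    # slice the centered window of the full convolution: np.convolve's
    # "same" mode returns the wrong length when the kernel outsizes the
    # signal (small template banks)
    start = (len(kernel) - 1) // 2
    num = np.convolve(raw, kernel, mode="full")[start : start + len(raw)]
    den = np.convolve(np.ones_like(raw), kernel, mode="full")[start : start + len(raw)]
    return num / den


@dataclass
class MSTdState:
    """Activations of the MSTd field plus the temporally averaged drive."""

    x: np.ndarray
    input_trace: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "MSTdState":
        return cls(x=np.zeros(n), input_trace=np.zeros(n))


def step_dynamics(
    state: MSTdState, drive: np.ndarray, params: ModelParams
) -> MSTdState:
    """Advance the recurrent shunting field by one stimulus frame.

    The drive is folded into the exponential moving average
    ``trace <- c * trace + (1 - c) * drive`` once per frame, then the field
    integrates ``substeps_per_frame`` steps of size ``dt``.  Integration is
    a positivity-preserving semi-implicit Euler scheme (decay and
    inhibition treated implicitly), which keeps every activation in
    [0, B] unconditionally — the contrast-enhancing signal function makes
    the explicit form stiff near the ceiling.
    """
    if not np.all(np.isfinite(drive)):
        raise FloatingPointError("non-finite drive")
    trace = params.c_avg * state.input_trace + (1.0 - params.c_avg) * drive
    x = state.x.copy()
    A, B, dt = params.a_decay, params.b_ceiling, params.dt
    f = params.signal_fn
    for _ in range(params.substeps_per_frame):
        fx = f(x)
        excit = trace + fx
        inhib = fx.sum() - fx
        x = (x + dt * B * excit) / (1.0 + dt * (A + excit + inhib))
    return MSTdState(x=x, input_trace=trace)


@dataclass(frozen=True)
class HeadingEstimate:
    value: float
    frame: int


def decode_heading(state: MSTdState, bank: TemplateBank, frame: int = 0) -> HeadingEstimate:
    """Population-vector readout: activation-weighted mean preferred heading."""
    total = state.x.sum()
    if total <= 0.0:
        raise UndefinedEstimateError("all-zero activation: heading undefined")
    return HeadingEstimate(value=float(state.x @ bank.headings / total), frame=frame)


@dataclass
class TrialResult:
    """Decoded headings of one trial at each requested readout frame."""

    spec: object
    estimates: list[HeadingEstimate]

    def judged(self, frame: int) -> float:
        for est in self.estimates:
            if est.frame == frame:
                return est.value
        raise KeyError(f"no readout at frame {frame}")


def run_trial(
    sample: FlowSample,
    params: ModelParams | None = None,
    readout_frames: Sequence[int] = (),
    bank: TemplateBank | None = None,
) -> TrialResult:
    """Run one flow sample through the full model.

    The state starts from rest; per frame the pipeline is MT pooling,
    template match, cross-heading smoothing and one frame of recurrent
    dynamics.  Blackout frames deliver zero drive, so the state evolves on
    the recurrent interactions alone.  The heading is decoded after each
    frame listed in ``readout_frames`` (1-based).
    """
    params = params or ModelParams()
    if bank is None:
        bank = build_templates(sample.flow.shape[1])
    readout = set(readout_frames)
    if any(f < 1 or f > sample.n_frames for f in readout):
        raise ValueError("readout frame outside the trial")
    state = MSTdState.zeros(bank.n_templates)
    estimates: list[HeadingEstimate] = []
    for t in range(1, sample.n_frames + 1):
        if sample.valid_mask[t - 1]:
            pooled = mt_pool(sample.flow[t - 1], params)
            drive = smooth_activations(template_match(pooled, bank, params), params)
        else:
            drive = np.zeros(bank.n_templates)
        state = step_dynamics(state, drive, params)
        if t in readout:
            estimates.append(decode_heading(state, bank, frame=t))
    return TrialResult(spec=sample.spec, estimates=estimates)
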