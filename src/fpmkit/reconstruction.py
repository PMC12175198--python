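"""Joint gradient-based FPM reconstruction ("physical network" style).

The reconstructor treats the forward capture model as a differentiable
computation graph whose free parameters are the HR object spectrum, the
pupil's Zernike coefficients, the defocus distance z and the per-capture
log intensity factors, and minimizes the data misfit

    ε = (1/B) Σ_{i ∈ batch} mean_px | I_pred,i − I_gt,i |      (L1, default)
      = (1/B) Σ_{i ∈ batch} mean_px ( I_pred,i − I_gt,i )²     (L2)

with the Adam optimizer over mini-batches of LED indices.  Gradients are
exact Wirtinger derivatives propagated analytically through the capture
chain (spectrum crop → pupil/defocus product → unitary inverse FFT →
intensity); for a complex parameter p the optimizer receives 2·∂ε/∂p*,
which equals the gradient with respect to (Re p, Im p).

The intensity factors are special: a dark-field capture is orders of
magnitude dimmer than a bright-field one, and its γ trades off against the
part of the spectrum only that capture sees, which makes pure gradient
descent on log γ extremely slow to identify them.  By default γ is instead
refreshed once per epoch with the classic closed-form LED intensity
correction — each γ_i is multiplied by the ratio of measured to predicted
mean frame brightness (``OptimizerSpec.gamma_update = "ratio"``); plain
Adam updates on log γ remain available (``"adam"``).

Initialization follows the standard recipe: the recovered amplitude starts
from the central-LED frame (square root, Fourier-upsampled, zero phase),
defocus starts at zero, and the pupil starts as a Zernike expansion with
only the piston coefficient set to 1.  Intensity factors are positive by
construction (optimized as log γ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import CaptureStack, ComplexObject, ObjectSpectrum, shift_pixels
from .zernike import zernike_basis

__all__ = [
    "OptimizerSpec",
    "ReconstructionState",
    "ReconstructionDiverged",
    "initialize_state",
    "objective",
    "reconstruct",
    "extract_object",
    "ExtractedObject",
]

PARAM_GROUPS = ("spectrum", "pupil", "z", "gamma")

DEFAULT_LEARNING_RATES = {
    "spectrum": 1e-2,
    "pupil": 1e-3,
    "z": 1e-1,       # μm per unit step
    "gamma": 1e-3,   # on log γ
}


@dataclass(frozen=True)
class OptimizerSpec:
    """Optimization schedule for :func:`reconstruct`.

    ``freeze`` names parameter groups (subset of ``{"spectrum", "pupil",
    "z", "gamma"}``) excluded from the update; frozen groups are returned
    bit-identical to their initial values.
    """

    loss_kind: str = "l1"
    learning_rates: dict = field(default_factory=lambda: dict(DEFAULT_LEARNING_RATES))
    epochs: int = 200
    batch_size: int = 13
    seed: int = 0
    freeze: frozenset = frozenset()
    n_zernike: int = 15
    gamma_update: str = "ratio"

    def __post_init__(self) -> None:
        if self.loss_kind not in ("l1", "l2"):
            raise ValueError("loss_kind must be 'l1' or 'l2'")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        unknown = set(self.freeze) - set(PARAM_GROUPS)
        if unknown:
            raise ValueError(f"unknown parameter groups in freeze: {sorted(unknown)}")
        if self.gamma_update not in ("ratio", "adam"):
            raise ValueError("gamma_update must be 'ratio' or 'adam'")


@dataclass
class ReconstructionState:
    """Current estimates of all jointly optimized quantities."""

    spectrum: ObjectSpectrum
    zernike_coeffs: np.ndarray
    z: float
    gammas: np.ndarray
    loss_history: list = field(default_factory=list)
    epoch: int = 0


class ReconstructionDiverged(RuntimeError):
    def __init__(self, epoch: int, learning_rates: dict):
        self.epoch = epoch
        self.learning_rates = dict(learning_rates)
        super().__init__(
            f"non-finite loss at epoch {epoch} with learning rates "
            f"{self.learning_rates}")


# --------------------------------------------------------------------------
# initialization
# --------------------------------------------------------------------------

def _fourier_upsample(img: np.ndarray, factor: int) -> np.ndarray:
    """Band-limited upsampling by zero-padding the orthonormal spectrum."""
    n = img.shape[0]
    big = n * factor
    spec = np.fft.fftshift(np.fft.fft2(img, norm="ortho"))
    pad = np.zeros((big, big), dtype=complex)
    lo = big // 2 - n // 2
    pad[lo:lo + n, lo:lo + n] = spec
    return np.fft.ifft2(np.fft.ifftshift(pad), norm="ortho") * factor


def initialize_state(stack: CaptureStack, n_zernike: int = 15) -> ReconstructionState:
    """Standard FPM starting point.

    Amplitude = upsampled square root of the central-LED frame with zero
    phase; z = 0; Zernike coefficients (1, 0, …, 0); γ ≡ 1.
    """
    if stack.illumination.central_index >= len(stack.images):
        raise ValueError("stack is missing the central-LED frame")
    cfg = stack.config
    central = stack.images[stack.illumination.central_index]
    amp = _fourier_upsample(np.sqrt(np.clip(central, 0, None)), cfg.hr_upsample)
    spec = np.fft.fftshift(np.fft.fft2(amp, norm="ortho"))
    coeffs = np.zeros(n_zernike)
    coeffs[0] = 1.0
    return ReconstructionState(
        spectrum=ObjectSpectrum(values=spec, k_sampling=cfg.dk),
        zernike_coeffs=coeffs,
        z=0.0,
        gammas=np.ones(len(stack.images)),
    )


# --------------------------------------------------------------------------
# batched forward/backward pass
# --------------------------------------------------------------------------

class _Model:
    """Precomputed grids plus the batched differentiable forward pass."""

    def __init__(self, stack: CaptureStack, n_zernike: int):
        cfg = stack.config
        self.cfg = cfg
        self.n = cfg.lr_side
        self.big = cfg.hr_side
        self.u = cfg.hr_upsample
        kx, ky = cfg.lr_freq_grid()
        kr = np.hypot(kx, ky)
        self.support = kr <= cfg.cutoff
        rho = kr / cfg.cutoff
        theta = np.arctan2(ky, kx)
        self.zbasis = zernike_basis(n_zernike, rho, theta) * self.support
        lam = cfg.wavelength
        radicand = 1.0 - (lam * kx) ** 2 - (lam * ky) ** 2
        self.radicand = radicand
        self.prop = radicand >= 0
        self.kz = np.where(self.prop, np.sqrt(np.clip(radicand, 0, None)), 0.0)
        self.kx, self.ky = kx, ky
        # per-LED crop-window index grids
        shifts = shift_pixels(cfg, stack.illumination.wavevectors)
        c = self.big // 2
        n = self.n
        r0 = c + shifts[:, 1] - n // 2
        c0 = c + shifts[:, 0] - n // 2
        if (r0 < 0).any() or (c0 < 0).any() or (r0 + n > self.big).any() \
                or (c0 + n > self.big).any():
            bad = int(np.nonzero((r0 < 0) | (c0 < 0) | (r0 + n > self.big)
                                 | (c0 + n > self.big))[0][0])
            raise ValueError(f"spectral window for LED index {bad} extends "
                             "beyond the HR spectrum bounds")
        ar = np.arange(n)
        self.rows = r0[:, None] + ar[None, :]      # (N, n)
        self.cols = c0[:, None] + ar[None, :]

    def pupil_values(self, coeffs: np.ndarray) -> np.ndarray:
        phase = np.tensordot(coeffs, self.zbasis, axes=1)
        return np.where(self.support, np.exp(1j * phase), 0.0)

    def kernel_values(self, z: float) -> np.ndarray:
        lam = self.cfg.wavelength
        h = np.empty(self.prop.shape, dtype=complex)
        h[self.prop] = np.exp(1j * 2 * np.pi / lam * z * self.kz[self.prop])
        ev = ~self.prop
        h[ev] = np.exp(-2 * np.pi / lam * abs(z)
                       * np.sqrt(-self.radicand[ev]))
        return h

    def forward(self, spectrum: np.ndarray, coeffs: np.ndarray, z: float,
                log_gammas: np.ndarray, batch: np.ndarray):
        P = self.pupil_values(coeffs)
        H = self.kernel_values(z)
        W = spectrum[self.rows[batch][:, :, None], self.cols[batch][:, None, :]]
        phi = W * (P * H)[None]
        psi = np.fft.ifft2(np.fft.ifftshift(phi, axes=(-2, -1)),
                           norm="ortho", axes=(-2, -1)) / self.u
        gam = np.exp(log_gammas[batch])
        intens = gam[:, None, None] * np.abs(psi) ** 2
        cache = (P, H, W, psi, gam)
        return intens, cache

    def loss_and_grads(self, spectrum, coeffs, z, log_gammas, images, batch,
                       loss_kind, freeze):
        intens, (P, H, W, psi, gam) = self.forward(spectrum, coeffs, z,
                                                   log_gammas, batch)
        gt = images[batch]
        diff = intens - gt
        npix = diff[0].size
        b = len(batch)
        if loss_kind == "l1":
            loss = float(np.abs(diff).mean(axis=(-2, -1)).mean())
            G = np.sign(diff) / (b * npix)
        else:
            loss = float((diff ** 2).mean(axis=(-2, -1)).mean())
            G = 2.0 * diff / (b * npix)

        grads = {}
        # dε/dψ* , then pull back through the unitary transform
        g_psi = G * gam[:, None, None] * psi
        g_phi = np.fft.fftshift(np.fft.fft2(g_psi, norm="ortho", axes=(-2, -1)),
                                axes=(-2, -1)) / self.u
        if "spectrum" not in freeze:
            g_w = g_phi * np.conj(P * H)[None]
            g_spec = np.zeros_like(spectrum)
            np.add.at(g_spec,
                      (self.rows[batch][:, :, None], self.cols[batch][:, None, :]),
                      2.0 * g_w)
            grads["spectrum"] = g_spec
        if "pupil" not in freeze:
            g_p = (g_phi * np.conj(W * H[None])).sum(axis=0)
            t = np.imag(P * np.conj(g_p))
            grads["pupil"] = -2.0 * np.tensordot(self.zbasis, t, axes=([1, 2], [0, 1]))
        if "z" not in freeze:
            g_h = (g_phi * np.conj(W * P[None])).sum(axis=0)
            dh_dz = 1j * 2 * np.pi / self.cfg.wavelength * self.kz \
                * self.kernel_values(z)
            grads["z"] = 2.0 * float(np.sum(np.real(np.conj(g_h) * dh_dz)))
        if "gamma" not in freeze:
            gg = np.zeros_like(log_gammas)
            gg[batch] = (G * intens).sum(axis=(-2, -1))
            grads["gamma"] = gg
        return loss, grads


# --------------------------------------------------------------------------
# objective and optimizer
# --------------------------------------------------------------------------

def objective(state: ReconstructionState, stack: CaptureStack,
              batch: np.ndarray | list[int] | None = None,
              loss_kind: str = "l1") -> float:
    """Data misfit of the state's predictions on a batch of LED indices."""
    batch = np.arange(len(stack.images)) if batch is None else np.asarray(batch)
    if batch.size == 0:
        raise ValueError("batch must be nonempty")
    model = _Model(stack, len(state.zernike_coeffs))
    intens, _ = model.forward(state.spectrum.values, state.zernike_coeffs,
                              state.z, np.log(state.gammas), batch)
    diff = intens - stack.images[batch]
    if loss_kind == "l1":
        return float(np.abs(diff).mean(axis=(-2, -1)).mean())
    if loss_kind == "l2":
        return float((diff ** 2).mean(axis=(-2, -1)).mean())
    raise ValueError("loss_kind must be 'l1' or 'l2'")


class _Adam:
    """Adam with complex support (second moment on |g|²)."""

    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = None
        self.v = None
        self.t = 0

    def step(self, param, grad):
        if self.m is None:
            self.m = np.zeros_like(param)
            self.v = np.zeros(np.shape(param))
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * np.abs(grad) ** 2
        mhat = self.m / (1 - self.b1 ** self.t)
        vhat = self.v / (1 - self.b2 ** self.t)
        return param - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def reconstruct(stack: CaptureStack, spec: OptimizerSpec | None = None, *,
                z_init: float = 0.0,
                state: ReconstructionState | None = None) -> ReconstructionState:
    """Jointly recover spectrum, pupil coefficients, defocus and γ by Adam.

    Runs ``spec.epochs`` passes over shuffled mini-batches of LED indices;
    deterministic given ``spec.seed``.  ``z_init`` (or an explicit starting
    ``state``) sets the initial defocus — useful with ``freeze={"z"}`` for
    reconstructing at a chosen focal plane.
    """
    spec = spec or OptimizerSpec()
    if spec.batch_size > len(stack.images):
        raise ValueError("batch_size exceeds the number of captures")
    if state is None:
        state = initialize_state(stack, n_zernike=spec.n_zernike)
        state.z = float(z_init)
    model = _Model(stack, len(state.zernike_coeffs))

    params = {
        "spectrum": state.spectrum.values.copy(),
        "pupil": state.zernike_coeffs.astype(float).copy(),
        "z": float(state.z),
        "gamma": np.log(state.gammas.astype(float)),
    }
    gamma_by_ratio = "gamma" not in spec.freeze and spec.gamma_update == "ratio"
    grad_freeze = spec.freeze | {"gamma"} if gamma_by_ratio else spec.freeze
    opts = {g: _Adam(spec.learning_rates.get(g, DEFAULT_LEARNING_RATES[g]))
            for g in PARAM_GROUPS if g not in grad_freeze}
    rng = np.random.default_rng(spec.seed)
    n_led = len(stack.images)
    all_leds = np.arange(n_led)
    history = []
    for epoch in range(spec.epochs):
        order = rng.permutation(n_led)
        epoch_losses = []
        for lo in range(0, n_led, spec.batch_size):
            batch = order[lo:lo + spec.batch_size]
            loss, grads = model.loss_and_grads(
                params["spectrum"], params["pupil"], params["z"],
                params["gamma"], stack.images, batch, spec.loss_kind,
                grad_freeze)
            if not np.isfinite(loss):
                raise ReconstructionDiverged(epoch, spec.learning_rates)
            epoch_losses.append(loss)
            for g, opt in opts.items():
                params[g] = opt.step(params[g], grads[g])
            params["z"] = float(params["z"])
        if gamma_by_ratio:
            # classic LED intensity correction: close the per-frame mean
            # brightness gap in one multiplicative step per epoch
            pred, _ = model.forward(params["spectrum"], params["pupil"],
                                    params["z"], params["gamma"], all_leds)
            ratio = stack.images.mean(axis=(1, 2)) \
                / np.maximum(pred.mean(axis=(1, 2)), 1e-300)
            params["gamma"] = params["gamma"] + np.log(ratio)
        history.append(float(np.mean(epoch_losses)))

    return ReconstructionState(
        spectrum=ObjectSpectrum(values=params["spectrum"],
                                k_sampling=stack.config.dk),
        zernike_coeffs=params["pupil"],
        z=float(params["z"]),
        gammas=np.exp(params["gamma"]),
        loss_history=state.loss_history + history,
        epoch=state.epoch + spec.epochs,
    )


# --------------------------------------------------------------------------
# output extraction
# --------------------------------------------------------------------------

@dataclass
class ExtractedObject:
    object: ComplexObject
    intensity: np.ndarray
    phase: np.ndarray
    clipped_pixels: int


def extract_object(state: ReconstructionState,
                   pixel_size: float | None = None) -> ExtractedObject:
    """Invert the spectrum estimate into intensity, phase and absorption.

    The phase map is reported in (−π, π] with the global piston removed
    (mean phase set to zero); absorption μ = −log|o| is clipped below at 0
    and the number of clipped pixels reported.
    """
    o = state.spectrum.to_field()
    intensity = np.abs(o) ** 2
    raw_phase = np.angle(o)
    phase = np.angle(np.exp(1j * (raw_phase - raw_phase.mean())))
    amp = np.abs(o)
    with np.errstate(divide="ignore"):
        mu = -np.log(np.clip(amp, 1e-300, None))
    clipped = int(np.count_nonzero(mu < 0))
    mu = np.clip(mu, 0.0, None)
    n = o.shape[0]
    px = pixel_size if pixel_size is not None else 1.0 / (n * state.spectrum.k_sampling)
    obj = ComplexObject(phase=phase, absorption=mu, pixel_size=px)
    return ExtractedObject(object=obj, intensity=intensity, phase=phase,
                           clipped_pixels=clipped)
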