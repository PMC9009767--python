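"""Gain-modulated activation functions.

Cortical arousal is modelled as a single *global gain* scalar ``delta``
that multiplies the output of every activation function in the network
simultaneously — the network analogue of a diffuse, spatially unspecific
neuromodulatory drive. ``delta = 1`` is the neutral state the network is
trained in; sweeping ``delta`` at inference probes how over- or
under-aroused processing changes task performance.

Two activation families are supported:

* ``rectifier`` — the plain ReLU, ``f(S) = delta * max(0, S)``.
* ``saturating`` — a biologically motivated bounded variant,
  ``f(S) = delta * A_max * tanh(max(0, S) / A_max)``, which tracks the
  rectifier closely for small inputs (within ~1.4 % on ``S in [0, 1]``
  for the default ceiling ``A_max = 5``) but saturates at ``A_max``,
  mimicking the firing-rate ceiling of real neurons. The ceiling is what
  lets high gain states *compress* information rather than merely
  rescale it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "GlobalGainState",
    "ActivationSpec",
    "gained_activation",
    "activation_grad",
]


@dataclass
class GlobalGainState:
    """The single gain scalar shared by every activation site of a model."""

    delta: float = 1.0

    def __post_init__(self) -> None:
        self.set(self.delta)

    def set(self, delta: float) -> None:
        delta = float(delta)
        if not np.isfinite(delta) or delta <= 0:
            raise ValueError(f"global gain delta must be finite and > 0, got {delta}")
        self.delta = delta


@dataclass(frozen=True)
class ActivationSpec:
    """Configuration of the (pre-gain) activation nonlinearity.

    Parameters
    ----------
    kind
        ``"rectifier"`` or ``"saturating"``.
    a_max
        Response ceiling of the saturating variant (supremum of the
        unsaturated response); ignored for the rectifier.
    constants
        Optional free slot for alternative saturating parameterisations
        (e.g. constants fitted to a spiking-neuron response curve); the
        default family only uses ``a_max``.
    """

    kind: str = "saturating"
    a_max: float = 5.0
    constants: Optional[Mapping[str, float]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("rectifier", "saturating"):
            raise ValueError(f"unknown activation kind {self.kind!r}")
        if self.kind == "saturating" and self.a_max <= 0:
            raise ValueError("a_max must be > 0")


def _core(S: np.ndarray, spec: ActivationSpec) -> np.ndarray:
    """The gain-free nonlinearity g(S): non-negative and non-decreasing."""
    r = np.maximum(S, 0.0)
    if spec.kind == "rectifier":
        return r
    a = spec.a_max
    return a * np.tanh(r / a)


def gained_activation(
    S: np.ndarray, spec: ActivationSpec, gain: GlobalGainState
) -> np.ndarray:
    """Apply the gain-scaled activation ``delta * g(S)`` elementwise.

    Raises on non-finite input: NaNs propagating through a sweep would
    silently corrupt every downstream profile.
    """
    S = np.asarray(S)
    if not np.all(np.isfinite(S)):
        raise FloatingPointError("non-finite values in activation input")
    return gain.delta * _core(S, spec)


def activation_grad(S: np.ndarray, spec: ActivationSpec) -> np.ndarray:
    """d g(S) / dS, used by backprop (the gain factor is applied outside)."""
    pos = S > 0
    if spec.kind == "rectifier":
        return pos.astype(S.dtype)
    a = spec.a_max
    t = np.tanh(np.maximum(S, 0.0) / a)
    return np.where(pos, 1.0 - t * t, 0.0).astype(S.dtype)
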