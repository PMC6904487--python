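"""Joint frequency/phase flicker design for an SSVEP virtual keyboard.

Each key of the speller is tagged with sinusoidal luminance flicker at a
unique frequency/phase pair drawn from linear schedules

    f_i   = f0 + delta_f * (i - 1)
    phi_i = (phi0 + delta_phi * (i - 1)) mod 2*pi

for 1-based key index ``i``.  With the default 28-key QWERTY layout and the
schedules ``f0 = 10.0 Hz, delta_f = 0.2 Hz`` and ``phi0 = 1.5*pi,
delta_phi = 0.35*pi`` the keys span 10.0 Hz/1.5*pi through 15.4 Hz/0.95*pi.

The key-to-frequency spatial mapping follows QWERTY reading order
(left-to-right, top-to-bottom, then backspace, then space); any other
mapping can be obtained by passing a custom ``key_order``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "BACKSPACE",
    "SPACE",
    "FlickerSpec",
    "build_flicker_spec",
    "luminance",
    "qwerty_layout",
]

#: Symbol used for the backspace key in layouts and transcripts.
BACKSPACE = "<"
#: Symbol used for the space key.
SPACE = " "

_QWERTY_ROWS = ("QWERTYUIOP", "ASDFGHJKL", "ZXCVBNM")


def qwerty_layout() -> list[str]:
    """Return the 28 speller key symbols in QWERTY reading order.

    Rows Q..P, A..L, Z..M followed by backspace (``"<"``) and space
    (``" "``); 28 unique symbols in total.
    """
    keys = [ch for row in _QWERTY_ROWS for ch in row]
    keys.append(BACKSPACE)
    keys.append(SPACE)
    return keys


@dataclass(frozen=True)
class FlickerSpec:
    """Per-key flicker frequency and phase assignment.

    Attributes
    ----------
    n_keys : int
        Number of flickering keys.
    f0, delta_f : float
        Base frequency (Hz) and per-key increment (Hz).
    phi0, delta_phi : float
        Base phase (rad) and per-key increment (rad).
    key_order : list of str
        Key symbols in assignment order (index ``i`` gets ``key_order[i-1]``).
    frequencies, phases : ndarray
        Per-key frequency (Hz) and phase (rad, reduced to ``[0, 2*pi)``).
    """

    n_keys: int
    f0: float
    delta_f: float
    phi0: float
    delta_phi: float
    key_order: list[str]
    frequencies: np.ndarray = field(repr=False)
    phases: np.ndarray = field(repr=False)

    def key_index(self, symbol: str) -> int:
        """1-based index of ``symbol`` in the layout."""
        try:
            return self.key_order.index(symbol) + 1
        except ValueError:
            raise KeyError(f"symbol {symbol!r} is not in the keyboard layout") from None

    @property
    def f1(self) -> float:
        """Lowest flicker frequency (Hz)."""
        return float(self.frequencies[0])

    @property
    def f_max(self) -> float:
        """Highest flicker frequency (Hz)."""
        return float(self.frequencies[-1])

    def to_yaml(self, path) -> None:
        """Serialize to a plain YAML mapping (phases in units of pi)."""
        payload = {
            "n_keys": int(self.n_keys),
            "f0": float(self.f0),
            "delta_f": float(self.delta_f),
            "phi0_pi_units": float(self.phi0 / np.pi),
            "delta_phi_pi_units": float(self.delta_phi / np.pi),
            "key_order": list(self.key_order),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False, default_flow_style=False)

    @classmethod
    def from_yaml(cls, path) -> "FlickerSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return build_flicker_spec(
            n_keys=payload["n_keys"],
            f0=payload["f0"],
            delta_f=payload["delta_f"],
            phi0=payload["phi0_pi_units"] * np.pi,
            delta_phi=payload["delta_phi_pi_units"] * np.pi,
            key_order=payload.get("key_order"),
        )


def build_flicker_spec(
    n_keys: int = 28,
    f0: float = 10.0,
    delta_f: float = 0.2,
    phi0: float = 1.5 * np.pi,
    delta_phi: float = 0.35 * np.pi,
    key_order: list[str] | None = None,
) -> FlickerSpec:
    """Construct the joint frequency/phase assignment for ``n_keys`` keys.

    Parameters follow the linear schedules described in the module
    docstring.  ``key_order`` defaults to the QWERTY reading order when
    ``n_keys == 28``, otherwise to generic ``K1..Kn`` placeholders.

    Raises
    ------
    ValueError
        If ``n_keys < 1``, ``f0 <= 0`` or ``delta_f < 0``.
    """
    if n_keys < 1:
        raise ValueError(f"n_keys must be >= 1, got {n_keys}")
    if f0 <= 0:
        raise ValueError(f"f0 must be positive, got {f0}")
    if delta_f < 0:
        raise ValueError(f"delta_f must be non-negative, got {delta_f}")
    if key_order is None:
        key_order = qwerty_layout() if n_keys == 28 else [f"K{i}" for i in range(1, n_keys + 1)]
    if len(key_order) != n_keys:
        raise ValueError(f"key_order has {len(key_order)} symbols, expected {n_keys}")
    if len(set(key_order)) != n_keys:
        raise ValueError("key_order contains duplicate symbols")

    i = np.arange(1, n_keys + 1)
    frequencies = f0 + delta_f * (i - 1)
    phases = np.mod(phi0 + delta_phi * (i - 1), 2 * np.pi)
    phases = np.where(phases >= 2 * np.pi, 0.0, phases)  # guard float round-up at the wrap
    return FlickerSpec(
        n_keys=n_keys,
        f0=f0,
        delta_f=delta_f,
        phi0=phi0,
        delta_phi=delta_phi,
        key_order=list(key_order),
        frequencies=frequencies,
        phases=phases,
    )


def luminance(t, key_index: int, spec: FlickerSpec):
    """Sinusoidal key luminance at time ``t`` seconds since flicker onset.

    ``lum(t) = (1 + sin(2*pi*f_i*t + phi_i)) / 2``, in [0, 1].

    ``t`` may be a scalar or array.  ``key_index`` is 1-based.
    """
    if not 1 <= key_index <= spec.n_keys:
        raise ValueError(f"key_index {key_index} out of range 1..{spec.n_keys}")
    f = spec.frequencies[key_index - 1]
    phi = spec.phases[key_index - 1]
    return 0.5 * (1.0 + np.sin(2 * np.pi * f * np.asarray(t, dtype=float) + phi))
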