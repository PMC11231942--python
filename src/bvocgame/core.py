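"""Shared fitness mathematics of the BVOC emission game.

Pure functions used by both the lattice and the mean-field model. Fitness is
the expected seed output of an individual: herbivory removes a fraction of
seed production, and that fraction is attenuated multiplicatively by the
plant's own signaling (emitters only, factor ``alpha1``) and by the signals
of nearby emitters (factor ``alpha2`` per emitter, compounded).

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "gross_inter_effect_local",
    "fitness_emitter",
    "fitness_nonemitter",
]


def gross_inter_effect_local(m_emitters, alpha2):
    """Gross inter-communication effect from ``m_emitters`` nearby emitters.

    Each emitting neighbor multiplies herbivory damage by ``alpha2``, so the
    combined attenuation is ``alpha2 ** m_emitters`` — 1 when no emitter is
    in range, approaching 0 as emitters accumulate.

    Parameters
    ----------
    m_emitters : int or ndarray of int
        Number of emitters within signaling range (focal plant excluded).
    alpha2 : float
        Per-emitter damage multiplier, 0 < alpha2 < 1.

    Returns
    -------
    float or ndarray in (0, 1].
    """
    m = np.asarray(m_emitters)
    if np.any(m < 0):
        raise ValueError("m_emitters must be >= 0")
    if not 0.0 < alpha2 < 1.0:
        raise ValueError(f"alpha2={alpha2!r} outside valid range (0, 1)")
    out = np.power(alpha2, m)
    return out if out.ndim else float(out)


def fitness_emitter(alpha1, gross_inter, p, c, fhat=1.0):
    """Expected seed output of a BVOC emitter.

    ``(1 - p * alpha1 * gross_inter) * (1 - c) * fhat``: herbivory damage
    ``p`` is attenuated by the plant's own signaling (``alpha1``) and by its
    emitting neighbors (``gross_inter``), and the emission cost ``c`` taxes
    the remainder.
    """
    return (1.0 - p * alpha1 * np.asarray(gross_inter)) * (1.0 - c) * fhat


def fitness_nonemitter(gross_inter, p, fhat=1.0):
    """Expected seed output of a non-emitter (cheater).

    ``(1 - p * gross_inter) * fhat``: no own-signal protection and no cost;
    only eavesdropping on neighbors' signals attenuates damage.
    """
    return (1.0 - p * np.asarray(gross_inter)) * fhat
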