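"""Hepcidin promoter model and the upstream signaling cascades.

Hepcidin transcription integrates two activators on its promoter: SMAD
(iron-sensing, downstream of BMP6) and STAT3 (inflammation-sensing, downstream
of LPS -> IL6).  The promoter is described by a thermodynamic state ensemble
over the four occupancy states {empty, S-bound, T-bound, ST-bound}; each state
carries a Boltzmann weight and a fold-activation, and the observed activity is
the weight-averaged activation.  The ensemble parameters are fixed constants
(previously calibrated on hepatoma-cell perturbation data) and are loaded from
configuration, never re-fitted here.
"""

from __future__ import annotations

from .params import PromoterParams

__all__ = [
    "promoter_activity", "smad_activity", "il6_induction_rate",
    "stat3_activation_rate",
]


def promoter_activity(S: float, T: float, p: PromoterParams) -> float:
    """Fold-activation of the hepcidin promoter at SMAD activity ``S`` and
    STAT3 activity ``T``.

    Returns ``(1 + w_S q_S S + w_T q_T T + w_ST ω q_S q_T S T) /
    (1 + q_S S + q_T T + ω q_S q_T S T)``; basal (S = T = 0) activity is 1,
    and the value is bounded between the smallest and largest of
    ``(1, w_S, w_T, w_ST)``.
    """
    if S < 0 or T < 0:
        raise ValueError("promoter activities must be >= 0")
    qs, qt = p.q_S * S, p.q_T * T
    qst = p.omega * qs * qt
    return (1.0 + p.w_S * qs + p.w_T * qt + p.w_ST * qst) / (1.0 + qs + qt + qst)


def smad_activity(BMP6: float, K_SMAD: float) -> float:
    """Algebraic SMAD activity: saturating in BMP6 with half-max at K_SMAD."""
    if BMP6 < 0:
        raise ValueError("BMP6 must be >= 0")
    if K_SMAD <= 0:
        raise ValueError("K_SMAD must be > 0")
    return BMP6 / (K_SMAD + BMP6)


def il6_induction_rate(LPS: float, IL6: float, s_IL6: float, K_IL6: float,
                       d_IL6: float) -> float:
    """d(IL6)/dt: saturating induction by LPS minus first-order decay."""
    if min(LPS, IL6, s_IL6, d_IL6) < 0 or K_IL6 <= 0:
        raise ValueError("il6_induction_rate requires non-negative inputs, K_IL6 > 0")
    return s_IL6 * LPS / (K_IL6 + LPS) - d_IL6 * IL6


def stat3_activation_rate(IL6: float, STAT3p: float, s_STAT: float,
                          K_STAT: float, d_STAT: float) -> float:
    """d(STAT3p)/dt: saturating activation by IL6 minus deactivation."""
    if min(IL6, STAT3p, s_STAT, d_STAT) < 0 or K_STAT <= 0:
        raise ValueError("stat3_activation_rate requires non-negative inputs, K_STAT > 0")
    return s_STAT * IL6 / (K_STAT + IL6) - d_STAT * STAT3p
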