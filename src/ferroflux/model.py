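"""Core state space and right-hand side of the whole-body iron model.

Twenty coupled ODEs describe seven organ iron pools (µg per animal,
standardized to a 25 g mouse), ferroportin mRNA and protein in four
Fpn-expressing compartments, and the regulatory layer (hepcidin, BMP6, IL6,
LPS, phosphorylated STAT3).  SMAD activity is an algebraic saturating function
of BMP6 (see :func:`ferroflux.promoter.smad_activity`).

Topology
--------
Serum is the central hub.  It feeds liver, spleen, duodenum, bone marrow and
the lumped "other organs" compartment by mass action; liver import carries an
additional supralinear NTBI component.  Liver, spleen, duodenum and "other"
export iron back to serum proportionally to their ferroportin level; the liver
exportable pool is capped by ferritin storage.  Bone marrow passes iron to red
blood cells (erythropoiesis) and, via ineffective erythropoiesis, to the
spleen; aging RBCs are recycled by splenic macrophages.  Dietary iron enters
the duodenal enterocyte pool through a saturable (Michaelis-Menten) uptake;
iron leaves the body by enterocyte shedding and skin desquamation.
"""

from __future__ import annotations

import numpy as np

from .params import ParameterSet
from .promoter import promoter_activity, smad_activity

__all__ = [
    "STATE_NAMES", "IRON_POOLS", "FPN_ORGANS", "N_STATES", "state_index",
    "flux_linear", "flux_export", "duodenal_uptake", "liver_export",
    "liver_import", "fpn_mrna_rate", "fpn_protein_rate", "rhs",
]

#: Iron pools, in µg per animal.
IRON_POOLS: tuple[str, ...] = (
    "Fe_serum", "Fe_liver", "Fe_spleen", "Fe_duodenum",
    "Fe_bm", "Fe_RBC", "Fe_other",
)

#: Compartments with explicit ferroportin expression.
FPN_ORGANS: tuple[str, ...] = ("liver", "spleen", "duo", "other")

#: The 20 dynamic species, in canonical order.  These identifiers are reused
#: by the observation map, the CSV dialect and the SBML export.
STATE_NAMES: tuple[str, ...] = IRON_POOLS + (
    "FpnmRNA_liver", "FpnmRNA_spleen", "FpnmRNA_duo", "FpnmRNA_other",
    "Fpn_liver", "Fpn_spleen", "Fpn_duo", "Fpn_other",
    "Hep", "BMP6", "IL6", "LPS", "STAT3p",
)

N_STATES: int = len(STATE_NAMES)
_IDX: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}


def state_index(name: str) -> int:
    """Index of a state name in the canonical ordering."""
    try:
        return _IDX[name]
    except KeyError:
        raise KeyError(f"unknown state {name!r}; valid states: {STATE_NAMES}") from None


# ----------------------------------------------------------------------
# Elementary flux laws.  These are the public, validated forms; the rhs
# inlines the same arithmetic for speed.
# ----------------------------------------------------------------------

def flux_linear(rate: float, pool: float) -> float:
    """Mass-action flux ``rate * pool`` (µg/h)."""
    if rate < 0 or pool < 0:
        raise ValueError("flux_linear requires rate >= 0 and pool >= 0")
    return rate * pool


def flux_export(u: float, pool: float, fpn: float) -> float:
    """Ferroportin-mediated export ``u * pool * fpn`` (µg/h)."""
    if u < 0 or pool < 0 or fpn < 0:
        raise ValueError("flux_export requires non-negative inputs")
    return u * pool * fpn


def duodenal_uptake(Fe_food: float, V_duo: float, K_duo: float) -> float:
    """Saturable uptake of dietary iron into enterocytes (µg/h).

    Michaelis-Menten in the dietary iron content: monotone increasing and
    bounded by ``V_duo``; half-saturation at ``Fe_food = K_duo``.
    """
    if K_duo <= 0:
        raise ValueError("K_duo must be > 0")
    if Fe_food < 0 or V_duo < 0:
        raise ValueError("duodenal_uptake requires non-negative inputs")
    return V_duo * Fe_food / (K_duo + Fe_food)


def liver_export(u_liver: float, Fpn_liver: float, Fe_liver: float,
                 Fe_max: float) -> float:
    """Liver-to-serum export with a ferritin storage cap (µg/h).

    Export is proportional to liver iron only up to ``Fe_max``; iron in excess
    is treated as ferritin-bound and unavailable for transfer to plasma.
    """
    if min(u_liver, Fpn_liver, Fe_liver, Fe_max) < 0:
        raise ValueError("liver_export requires non-negative inputs")
    return u_liver * Fpn_liver * min(Fe_liver, Fe_max)


def liver_import(Fe_serum: float, v_liver: float, v_NTBI: float,
                 K_NTBI: float, *, mode: str = "saturating",
                 Tf_cap: float = 8.0) -> float:
    """Serum-to-liver import: transferrin-bound plus NTBI component (µg/h).

    The default ``saturating`` mode uses the smooth supralinear form
    ``v_NTBI * Fe_serum**2 / (K_NTBI + Fe_serum)``, which is ~quadratic for
    serum iron well below ``K_NTBI`` and approaches ``(v_liver+v_NTBI)*Fe``
    far above it.  ``threshold`` mode uses a hard transferrin capacity:
    ``v_NTBI * max(0, Fe_serum - Tf_cap)``.
    """
    if K_NTBI <= 0:
        raise ValueError("K_NTBI must be > 0")
    if min(Fe_serum, v_liver, v_NTBI) < 0:
        raise ValueError("liver_import requires non-negative inputs")
    if mode == "saturating":
        ntbi = v_NTBI * Fe_serum * Fe_serum / (K_NTBI + Fe_serum)
    elif mode == "threshold":
        ntbi = v_NTBI * max(0.0, Fe_serum - Tf_cap)
    else:
        raise ValueError(f"unknown NTBI mode {mode!r}")
    return v_liver * Fe_serum + ntbi


def fpn_mrna_rate(a_o: float, LPS: float, K_LPS: float, d_mRNA: float,
                  mRNA: float) -> float:
    """Time derivative of Fpn mRNA: LPS-inhibited synthesis minus decay."""
    if min(a_o, LPS, d_mRNA, mRNA) < 0 or K_LPS <= 0:
        raise ValueError("fpn_mrna_rate requires non-negative inputs, K_LPS > 0")
    return a_o * K_LPS / (K_LPS + LPS) - d_mRNA * mRNA


def fpn_protein_rate(b_o: float, Fe_organ: float, K_IRE: float, mRNA: float,
                     k1: float, k2_o: float, Hep: float, Fpn: float) -> float:
    """Time derivative of Fpn protein.

    Translation is enhanced by intracellular iron (IRE/IRP, saturating with
    constant ``K_IRE``); degradation combines basal turnover ``k1`` with the
    hepcidin-triggered term ``k2_o * Hep``, giving an effective half-life of
    ``ln 2 / (k1 + k2_o * Hep)``.
    """
    if min(b_o, Fe_organ, mRNA, k1, k2_o, Hep, Fpn) < 0 or K_IRE <= 0:
        raise ValueError("fpn_protein_rate requires non-negative inputs, K_IRE > 0")
    return b_o * (Fe_organ / (K_IRE + Fe_organ)) * mRNA - (k1 + k2_o * Hep) * Fpn


# ----------------------------------------------------------------------
# Assembled right-hand side
# ----------------------------------------------------------------------

def _uptake(p: ParameterSet, fe_food: float) -> float:
    """Dietary uptake flux under the active model variant."""
    if p.linear_uptake:
        # Linear law anchored to coincide with the saturable law at the
        # normal diet (Fe_food = 1), so model variants share the baseline.
        return (p.V_duo / (p.K_duo + 1.0)) * fe_food
    return p.V_duo * fe_food / (p.K_duo + fe_food)


def rhs(t: float, y: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Time derivatives of the 20 model states (state units per hour).

    Negative concentrations are tolerated down to solver round-off (values are
    floored at zero inside the flux terms); NaNs raise immediately so the
    integrator fails loudly rather than silently.
    """
    if np.any(np.isnan(y)):
        raise FloatingPointError(f"NaN state encountered at t={t}")
    yc = np.maximum(y, 0.0)
    (fe_ser, fe_liv, fe_spl, fe_duo, fe_bm, fe_rbc, fe_oth,
     m_liv, m_spl, m_duo, m_oth,
     f_liv, f_spl, f_duo, f_oth,
     hep, bmp6, il6, lps, stat) = yc

    # --- iron fluxes (µg/h) ---
    uptake = _uptake(p, p.Fe_food)
    if p.ntbi_mode == "saturating":
        ntbi = p.v_NTBI * fe_ser * fe_ser / (p.K_NTBI + fe_ser)
    else:
        ntbi = p.v_NTBI * max(0.0, fe_ser - p.Tf_cap)
    imp_liv = p.v_liver * fe_ser + ntbi
    imp_spl = p.v_spleen * fe_ser
    imp_duo = p.v_duo * fe_ser
    imp_bm = p.v_bm * fe_ser
    imp_oth = p.v_other * fe_ser
    exp_liv = p.u_liver * f_liv * min(fe_liv, p.Fe_max)
    exp_spl = p.u_spleen * f_spl * fe_spl
    exp_duo = p.u_duo * f_duo * fe_duo
    exp_oth = p.u_other * f_oth * fe_oth
    bm_to_rbc = p.v_RBC * fe_bm
    bm_to_spl = p.v_splBM * fe_bm
    rbc_to_spl = p.v_splRBC * fe_rbc
    shed_duo = p.l_duo * fe_duo
    shed_oth = p.l_other * fe_oth

    dser = (exp_liv + exp_spl + exp_duo + exp_oth
            - imp_liv - imp_spl - imp_duo - imp_bm - imp_oth)
    dliv = imp_liv - exp_liv
    dspl = imp_spl + bm_to_spl + rbc_to_spl - exp_spl
    dduo = uptake + imp_duo - exp_duo - shed_duo
    dbm = imp_bm - bm_to_rbc - bm_to_spl
    drbc = bm_to_rbc - rbc_to_spl
    doth = imp_oth - exp_oth - shed_oth

    # --- Fpn expression ---
    lps_block = p.K_LPS / (p.K_LPS + lps)
    dm_liv = p.a_liver * lps_block - p.d_mRNA * m_liv
    dm_spl = p.a_spleen * lps_block - p.d_mRNA * m_spl
    dm_duo = p.a_duo * lps_block - p.d_mRNA * m_duo
    dm_oth = p.a_other * lps_block - p.d_mRNA * m_oth

    df_liv = p.b_liver * (fe_liv / (p.K_IRE + fe_liv)) * m_liv - (p.k1 + p.k2_liver * hep) * f_liv
    df_spl = p.b_spleen * (fe_spl / (p.K_IRE + fe_spl)) * m_spl - (p.k1 + p.k2_spleen * hep) * f_spl
    df_duo = p.b_duo * (fe_duo / (p.K_IRE + fe_duo)) * m_duo - (p.k1 + p.k2_duo * hep) * f_duo
    df_oth = p.b_other * (fe_oth / (p.K_IRE + fe_oth)) * m_oth - (p.k1 + p.k2_rest * hep) * f_oth

    # --- regulatory layer ---
    smad = 0.0 if p.smad_ko else smad_activity(bmp6, p.K_SMAD)
    dhep = p.s_hep * promoter_activity(smad, stat, p.promoter) - p.d_hep * hep
    dbmp6 = p.s_BMP6 * fe_liv / (p.K_BMP6 + fe_liv) - p.d_BMP6 * bmp6
    dil6 = p.s_IL6 * lps / (p.K_IL6 + lps) - p.d_IL6 * il6
    dlps = p.s_LPS - p.d_LPS * lps
    dstat = p.s_STAT * il6 / (p.K_STAT + il6) - p.d_STAT * stat

    out = np.array([
        dser, dliv, dspl, dduo, dbm, drbc, doth,
        dm_liv, dm_spl, dm_duo, dm_oth,
        df_liv, df_spl, df_duo, df_oth,
        dhep, dbmp6, dil6, dlps, dstat,
    ])
    if p.clamps:
        for name in p.clamps:
            out[_IDX[name]] = 0.0
    return out
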