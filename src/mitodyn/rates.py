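"""The 34 reaction and transport rate laws.

Every expression is reversible and thermodynamically balanced: its flux is
exactly zero when the mass-action ratio equals the apparent equilibrium
constant (Haldane consistency), with the membrane potential entering the
equilibrium condition of each electrogenic step.  Sign conventions follow
the biochemical equations as written (positive = forward); for transporters
positive means net movement into the matrix except where the written
equation says otherwise (ANT forward = ATP export, mNCE forward = Ca2+
efflux, mKHE forward = K+ efflux).

Units: concentrations M, fluxes nmol/min/mg protein, potential mV.

The scalar (non-transport) enzymes use a generalized reversible
Michaelis-Menten (convenience-kinetics) backbone

    J = Vf * fT * f_reg * (prod S / prod KmS - prod P / (prod KmS * Keq_app))
        / (prod(1 + S/KmS) + prod(1 + P/KmP) - 1)

with the regulatory mechanisms (Ca2+ activation of the dehydrogenases,
proton/adenine-nucleotide control of PDH, Pi activation of MDH and complex
III, OAA inhibition of SDH, ...) applied as documented multipliers.  The
electron-transport complexes, F1FO, ANT, the Ca2+/Na+/K+ cycle carriers and
the anion carriers each use the mechanistic form described in their
docstrings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .thermo import (KEQ_REF, R_GAS, FARADAY, default_dissociation_table)

__all__ = ["FLUX_NAMES", "RateContext", "tca_fluxes", "ets_fluxes",
           "phosphorylation_fluxes", "anion_transporter_fluxes",
           "cation_fluxes", "all_fluxes"]

FLUX_NAMES = (
    # mitochondrial reactions
    "PDH", "CS", "ACH", "IDH", "aKGDH", "SCoAS", "SDH", "FH", "MDH",
    "NDK", "GOT", "CI", "CIII", "CIV", "F1FO", "AK",
    # exchangers and ion channels
    "GAE", "OME", "PYRH", "GLUH", "CITMAL", "ISOCMAL", "SUCPI", "MALPI",
    "ANT", "PIC", "mHleak", "mKHE", "mKATP", "mKleak", "CaUNI", "mNCE",
    "mNHE",
    # other
    "HK",
)
assert len(FLUX_NAMES) == 34

_HREF = 1e-7   # reference proton concentration for dimensionless H ratios

# binding polynomials at the Keq reference condition (pH 7, 0.13 M K+,
# 1 mM free Mg2+), used to convert reference Keq values to local conditions
_PREF = {}


def _p_ref(lig):
    if lig not in _PREF:
        _PREF[lig] = default_dissociation_table().binding_polynomial(
            lig, 1e-7, K=0.13, Mg=1e-3)
    return _PREF[lig]


class DomainError(ValueError):
    pass


@dataclass
class RateContext:
    """Speciated model state handed to the rate laws.

    cx/ci/ce: total concentrations (M) by species base name per compartment
    (matrix / IMS / buffer); fx/fi/fe: free cation concentrations (M,
    keys H, K, Na, Mg, Ca); ligfree: fully unchelated ligand concentrations;
    poly: binding polynomial per ligand (matrix side).
    """

    cx: dict
    ci: dict
    ce: dict
    fx: dict
    fi: dict
    fe: dict
    ligfree_x: dict = field(default_factory=dict)
    ligfree_i: dict = field(default_factory=dict)
    poly_x: dict = field(default_factory=dict)
    dpsi: float = 0.0            # mV
    V_mtx: float = 0.65          # uL/mg
    T: float = 25.0              # C
    tf: dict = field(default_factory=dict)   # reaction -> temperature factor
    p: object = None             # ParameterSet
    khe_bose: bool = False
    o2_depleted: bool = False

    @property
    def u(self) -> float:
        """Dimensionless membrane potential F*dpsi/RT (negative energized)."""
        return FARADAY * self.dpsi * 1e-3 / (R_GAS * (273.15 + self.T))

    def keq_app(self, rid: str) -> float:
        """Apparent Keq of a scalar reaction at the local matrix conditions."""
        keq_ref, nu_h, ligs = KEQ_REF[rid]
        k = keq_ref * (_HREF / self.fx["H"]) ** nu_h
        for lig, st in ligs.items():
            if st == 0:
                continue
            p_now = self.poly_x.get(lig)
            if p_now is None:
                continue
            k *= (p_now / _p_ref(lig)) ** st
        return k


def _check_domain(ctx):
    if getattr(ctx, "_checked", False):
        return
    for comp in (ctx.cx, ctx.ci, ctx.ce):
        for name, v in comp.items():
            if v < 0:
                raise DomainError(f"negative concentration {name} = {v}")
    ctx._checked = True


def _rev_mm(vf, tf, subs, prods, kms, kmp, keq, freg=1.0):
    fwd = 1.0
    for s, km in zip(subs, kms):
        fwd *= s / km
    num_rev = 1.0
    for p_ in prods:
        num_rev *= p_
    for km in kms:
        num_rev /= km
    num_rev /= keq
    d_s = 1.0
    for s, km in zip(subs, kms):
        d_s *= 1.0 + s / km
    d_p = 1.0
    for p_, km in zip(prods, kmp):
        d_p *= 1.0 + p_ / km
    return vf * tf * freg * (fwd - num_rev) / (d_s + d_p - 1.0)


def _xi(zu: float) -> float:
    """GHK voltage factor zu/(exp(zu)-1), continuous at zero."""
    if abs(zu) < 1e-8:
        return 1.0 - 0.5 * zu
    if zu > 500.0:
        return 0.0
    if zu < -500.0:
        return -zu
    return zu / math.expm1(zu)


# ---------------------------------------------------------------------------
# TCA cycle and related matrix enzymes
# ---------------------------------------------------------------------------

def tca_fluxes(ctx: RateContext) -> dict:
    """PDH, CS, ACH, IDH, aKGDH, SCoAS, SDH, FH, MDH, NDK, GOT.

    The three calcium-sensitive dehydrogenases (PDH, IDH, aKGDH) carry a
    saturable free-Ca2+ activation multiplier normalized to 1 at saturating
    calcium, so raising matrix free Ca2+ never decreases their rates.
    """
    _check_domain(ctx)
    p = ctx.p
    cx = ctx.cx
    fx = ctx.fx
    tf = ctx.tf
    out = {}

    def ca_act(rid):
        a = p[rid, "a_Ca"]
        ka = p[rid, "Ka_Ca"]
        return (1.0 + a * fx["Ca"] / (ka + fx["Ca"])) / (1.0 + a)

    # PDH: proton, divalent-cation and adenine-nucleotide regulation
    f_h = p["PDH", "K_H"] / (p["PDH", "K_H"] + fx["H"])
    atp, adp = cx["ATP"], cx["ADP"]
    f_an = 1.0 / (1.0 + (atp / max(adp, 1e-12)) / p["PDH", "K_ratio_AN"])
    out["PDH"] = _rev_mm(
        p["PDH", "Vmax"], tf["PDH"],
        [cx["PYR"], cx["CoASH"], cx["NAD"]],
        [cx["AcCoA"], cx["NADH"]],
        [p["PDH", "Km_PYR"], p["PDH", "Km_CoA"], p["PDH", "Km_NAD"]],
        [p["PDH", "Ki_AcCoA"], p["PDH", "Ki_NADH"]],
        ctx.keq_app("PDH"), freg=ca_act("PDH") * f_h * f_an)

    out["CS"] = _rev_mm(
        p["CS", "Vmax"], tf["CS"],
        [cx["OAA"], cx["AcCoA"]], [cx["CoASH"], cx["CIT"]],
        [p["CS", "Km_OAA"], p["CS", "Km_AcCoA"]],
        [1e-2, p["CS", "Ki_CIT"]],
        ctx.keq_app("CS"))

    out["ACH"] = _rev_mm(
        p["ACH", "Vf"], tf["ACH"],
        [cx["CIT"]], [cx["ISOC"]],
        [p["ACH", "Km_CIT"]], [p["ACH", "Km_ISOC"]],
        ctx.keq_app("ACH"))

    # IDH: ADP and Ca2+ lower the apparent isocitrate Km
    km_app = p["IDH", "Km_ISOC"] / (1.0 + cx["ADP"] / p["IDH", "Ka_ADP"])
    out["IDH"] = _rev_mm(
        p["IDH", "Vmax"], tf["IDH"],
        [cx["ISOC"], cx["NAD"]], [cx["aKG"], cx["NADH"]],
        [km_app, p["IDH", "Km_NAD"]],
        [1e-2, p["IDH", "Ki_NADH"]],
        ctx.keq_app("IDH"), freg=ca_act("IDH"))

    f_adp = ((1.0 + p["aKGDH", "a_ADP"] * cx["ADP"]
              / (p["aKGDH", "Ka_ADP"] + cx["ADP"]))
             / (1.0 + p["aKGDH", "a_ADP"]))
    out["aKGDH"] = _rev_mm(
        p["aKGDH", "Vmax"], tf["aKGDH"],
        [cx["aKG"], cx["CoASH"], cx["NAD"]],
        [cx["SCoA"], cx["NADH"]],
        [p["aKGDH", "Km_aKG"], p["aKGDH", "Km_CoA"], p["aKGDH", "Km_NAD"]],
        [p["aKGDH", "Ki_SCoA"], p["aKGDH", "Ki_NADH"]],
        ctx.keq_app("aKGDH"), freg=ca_act("aKGDH") * f_adp)

    out["SCoAS"] = _rev_mm(
        p["SCoAS", "Vf"], tf["SCoAS"],
        [cx["SCoA"], cx["GDP"], cx["Pi"]],
        [cx["SUC"], cx["GTP"], cx["CoASH"]],
        [p["SCoAS", "Km_SCoA"], p["SCoAS", "Km_GDP"], p["SCoAS", "Km_Pi"]],
        [p["SCoAS", "Km_SUC"], p["SCoAS", "Km_GTP"], p["SCoAS", "Km_CoA"]],
        ctx.keq_app("SCoAS"))

    f_oaa = 1.0 / (1.0 + cx["OAA"] / p["SDH", "Ki_OAA"])
    out["SDH"] = _rev_mm(
        p["SDH", "Vf"], tf["SDH"],
        [cx["SUC"], cx["UQ"]], [cx["FUM"], cx["UQH2"]],
        [p["SDH", "Km_SUC"], p["SDH", "Km_UQ"]],
        [p["SDH", "Ki_FUM"], p["SDH", "Km_UQ"]],
        ctx.keq_app("SDH"), freg=f_oaa)

    out["FH"] = _rev_mm(
        p["FH", "Vf"], tf["FH"],
        [cx["FUM"]], [cx["MAL"]],
        [p["FH", "Km_FUM"]], [p["FH", "Km_MAL"]],
        ctx.keq_app("FH"))

    # MDH with the saturable Pi-activation mechanism
    a_pi = 1.0 + p["MDH", "a_Pi"] * cx["Pi"] / (p["MDH", "K_Pi"] + cx["Pi"])
    out["MDH"] = _rev_mm(
        p["MDH", "Vf"], tf["MDH"],
        [cx["MAL"], cx["NAD"]], [cx["OAA"], cx["NADH"]],
        [p["MDH", "Km_MAL"], p["MDH", "Km_NAD"]],
        [p["MDH", "Ki_OAA"], p["MDH", "Ki_NADH"]],
        ctx.keq_app("MDH"), freg=a_pi)

    out["NDK"] = _rev_mm(
        p["NDK", "Vf"], tf["NDK"],
        [cx["GTP"], cx["ADP"]], [cx["GDP"], cx["ATP"]],
        [p["NDK", "Km_GTP"], p["NDK", "Km_ADP"]],
        [p["NDK", "Km_GDP"], p["NDK", "Km_ATP"]],
        ctx.keq_app("NDK"))

    out["GOT"] = _rev_mm(
        p["GOT", "Vf"], tf["GOT"],
        [cx["ASP"], cx["aKG"]], [cx["OAA"], cx["GLU"]],
        [p["GOT", "Km_ASP"], p["GOT", "Km_aKG"]],
        [p["GOT", "Km_OAA"], p["GOT", "Km_GLU"]],
        ctx.keq_app("GOT"))
    return out


# ---------------------------------------------------------------------------
# electron transport system
# ---------------------------------------------------------------------------

def _ln(x):
    return math.log(max(x, 1e-300))


def ets_fluxes(ctx: RateContext) -> dict:
    """Complexes I, III and IV.

    Each flux is of the form  activity * (forward mass action - reverse
    mass action * r), where r collects the proton, charge (n_c * F * dpsi)
    and standard free-energy terms so that the flux vanishes exactly at the
    electrochemical equilibrium.  Charge stoichiometries per two electrons:
    CI 4, CIII 2, CIV 4 (10 charges per NADH oxidized).  Complex III
    carries the saturable matrix-Pi activation mechanism.
    """
    _check_domain(ctx)
    p = ctx.p
    cx, fi, fx = ctx.cx, ctx.fi, ctx.fx
    rt = R_GAS * (273.15 + ctx.T)
    fpsi = FARADAY * ctx.dpsi * 1e-3
    out = {}
    if ctx.o2_depleted:
        return {"CI": 0.0, "CIII": 0.0, "CIV": 0.0}

    hx, hi = fx["H"], fi["H"]
    nadh, nad = cx["NADH"], cx["NAD"]
    uq, uqh2 = cx["UQ"], cx["UQH2"]
    cred, cox = ctx.ci["cred"], ctx.ci["cox"]
    # kinetic voltage partition: pumping against a larger potential slows
    # the turnover symmetrically (the equilibrium point is untouched)
    alpha = p["general", "alpha_psi"]
    u = ctx.u

    # CI: NADH + UQ + 5 H_x -> NAD + UQH2 + 4 H_i ; 4 charges out
    lnk = (-p["general", "dG0_CI"] + 4.0 * fpsi) / rt
    r1 = math.exp(min(4.0 * _ln(hi) - 5.0 * _ln(hx) - lnk, 300.0))
    g1 = math.exp(min(alpha * 4.0 * u, 30.0))
    out["CI"] = (p["CI", "V"] * p["CI", "s_turn"] * ctx.tf["CI"] * g1
                 * (nadh * uq - nad * uqh2 * r1))

    # CIII: UQH2 + 2 cox + 2 H_x -> UQ + 2 cred + 4 H_i ; 2 charges out
    a_pi = 1.0 + (p["CIII", "a_Pi"] * cx["Pi"]
                  / (p["CIII", "K_Pi"] + cx["Pi"]))
    lnk = (-p["general", "dG0_CIII"] + 2.0 * fpsi) / rt
    r3 = math.exp(min(0.5 * (4.0 * _ln(hi) - 2.0 * _ln(hx) - lnk), 300.0))
    g3 = math.exp(min(alpha * 2.0 * u, 30.0))
    out["CIII"] = (p["CIII", "V"] * p["CIII", "s_turn"] * ctx.tf["CIII"] * a_pi * g3
                   * (math.sqrt(uqh2) * cox - math.sqrt(uq) * cred * r3))

    # CIV: 2 cred + 4 H_x + 1/2 O2 -> 2 cox + H2O + 2 H_i ; 4 charges out
    o2 = p["general", "O2"]
    lnk = (-p["general", "dG0_CIV"] + 4.0 * fpsi) / rt
    lnq = (2.0 * _ln(cox) + 2.0 * _ln(hi)
           - 2.0 * _ln(cred) - 4.0 * _ln(hx) - 0.5 * _ln(o2))
    ctot = cred + cox
    red_frac = cred / ctot if ctot > 0 else 0.0
    drive = 1.0 - math.exp(min(lnq - lnk, 60.0))
    g4 = math.exp(min(alpha * 4.0 * u, 30.0))
    out["CIV"] = (p["CIV", "V"] * p["CIV", "s_turn"] * ctx.tf["CIV"] * red_frac * g4
                  * o2 / (o2 + p["CIV", "K_O2"]) * drive)
    return out


# ---------------------------------------------------------------------------
# phosphorylation subsystem
# ---------------------------------------------------------------------------

def phosphorylation_fluxes(ctx: RateContext) -> dict:
    """F1FO ATP synthase, ANT, PIC, adenylate kinase, hexokinase.

    F1FO translocates n_A = 8/3 protons per ATP; when the proton motive
    force cannot sustain the matrix phosphorylation potential the same
    expression reverses and hydrolyzes ATP.  The ANT exchanges free
    (unchelated) ATP4- against ADP3- with the full membrane potential on
    the reverse (import) step, so ATP export is favored in an energized
    mitochondrion.
    """
    _check_domain(ctx)
    p = ctx.p
    cx, ci, ce = ctx.cx, ctx.ci, ctx.ce
    fx, fi = ctx.fx, ctx.fi
    rt = R_GAS * (273.15 + ctx.T)
    fpsi = FARADAY * ctx.dpsi * 1e-3
    out = {}

    # F1FO: ADP + Pi + nA H_i -> ATP + (nA-1) H_x ; nA charges in
    na = p["general", "n_F1FO"]
    lnk = (-p["general", "dG0_F1FO"] - na * fpsi) / rt
    ln_r = (na - 1.0) * _ln(fx["H"]) - na * _ln(fi["H"]) - lnk
    rterm = math.exp(min(ln_r, 200.0))
    fwd = cx["ADP"] * cx["Pi"]
    rev = cx["ATP"] * rterm
    out["F1FO"] = (p["F1FO", "V"] * ctx.tf["F1FO"] * p["F1FO", "c_sat"]
                   * (fwd - rev) / (p["F1FO", "K_drive"] + fwd + rev))

    # ANT: two-site electrogenic exchange of unchelated nucleotides; the
    # membrane potential partitions between the two ATP translocation
    # steps (theta on export, 1-theta on import) and also modulates the
    # ATP site occupancies, keeping |J| <= Vmax.
    atpx = ctx.ligfree_x.get("ATP", 0.0)
    adpx = ctx.ligfree_x.get("ADP", 0.0)
    atpi = ctx.ligfree_i.get("ATP", 0.0)
    adpi = ctx.ligfree_i.get("ADP", 0.0)
    th = p["ANT", "theta"]
    e_f = math.exp(max(min(-th * ctx.u, 50.0), -50.0))
    e_r = math.exp(max(min((1.0 - th) * ctx.u, 50.0), -50.0))
    d = ((atpx * e_f + adpx + p["ANT", "K0_x"])
         * (atpi * e_r + adpi + p["ANT", "K0_i"]))
    out["ANT"] = (p["ANT", "Vmax"] * ctx.tf["ANT"]
                  * (atpx * e_f * adpi - atpi * e_r * adpx) / d)

    # PIC: electroneutral Pi/2H+ cotransport (fast, near equilibrium)
    hri = fi["H"] / _HREF
    hrx = fx["H"] / _HREF
    out["PIC"] = (p["PIC", "Vmax"] * ctx.tf["PIC"]
                  * (ci["Pi"] * hri * hri - cx["Pi"] * hrx * hrx)
                  / (p["PIC", "Km_Pi"] + ci["Pi"] + cx["Pi"]))

    # adenylate kinase (IMS): 2 ADP <-> ATP + AMP
    k = p["AK", "Km"]
    keq_ak = KEQ_REF["AK"][0]
    d_ak = ((1.0 + ci["ADP"] / k) ** 2
            + (1.0 + ci["ATP"] / k) * (1.0 + ci["AMP"] / k) - 1.0)
    out["AK"] = (p["AK", "Vf"] * ctx.tf["AK"]
                 * (ci["ADP"] ** 2 - ci["ATP"] * ci["AMP"] / keq_ak)
                 / (k * k) / d_ak)

    # hexokinase (buffer-side ADP trap; buffer pH sets its apparent Keq)
    keq_hk = KEQ_REF["HK"][0] * (_HREF / ctx.fe["H"]) ** KEQ_REF["HK"][1]
    out["HK"] = _rev_mm(
        p["HK", "Vmax"], ctx.tf["HK"],
        [ce["GLC"], ce["ATP"]], [ce["G6P"], ce["ADP"]],
        [p["HK", "Km_GLC"], p["HK", "Km_ATP"]],
        [1e-2, 1e-3],
        keq_hk)
    return out


# ---------------------------------------------------------------------------
# anion transporters
# ---------------------------------------------------------------------------

def anion_transporter_fluxes(ctx: RateContext) -> dict:
    """GAE, OME, PYRH, GLUH, TCC (CIT/ISOC-MAL), DCC (SUC/MAL-Pi).

    GAE is the only electrogenic carrier here (net +1 charge into the
    matrix per glutamate imported) and is activated by external Ca2+;
    everything else is electroneutral and vanishes at its exchange
    equilibrium.
    """
    _check_domain(ctx)
    p = ctx.p
    cx, ci = ctx.cx, ctx.ci
    fx, fi, fe = ctx.fx, ctx.fi, ctx.fe
    hri = fi["H"] / _HREF
    hrx = fx["H"] / _HREF
    eu = math.exp(min(ctx.u, 50.0))
    out = {}

    # GAE: GLU_i + H_i + ASP_x -> GLU_x + H_x + ASP_i
    f_ca = 1.0 + (p["GAE", "a_Ca"] * fe["Ca"]
                  / (p["GAE", "Ka_Ca"] + fe["Ca"]))
    kg = p["GAE", "K_site"]
    d = (ci["GLU"] * hri + ci["ASP"] + kg) * (cx["GLU"] * hrx + cx["ASP"] + kg)
    out["GAE"] = (p["GAE", "V0"] * ctx.tf["GAE"] * f_ca
                  * (ci["GLU"] * hri * cx["ASP"]
                     - cx["GLU"] * hrx * ci["ASP"] * eu) / d)

    # OME: aKG_i + MAL_x <-> aKG_x + MAL_i (saturable, electroneutral)
    d = ((ci["aKG"] + cx["aKG"] + p["OME", "K_aKG"])
         * (ci["MAL"] + cx["MAL"] + p["OME", "K_MAL"]))
    out["OME"] = (p["OME", "Vf"] * ctx.tf["OME"]
                  * (ci["aKG"] * cx["MAL"] - cx["aKG"] * ci["MAL"]) / d)

    # proton cotransporters (mass-action activities, electroneutral)
    out["PYRH"] = (p["PYRH", "A"] * ctx.tf["PYRH"]
                   * (ci["PYR"] * fi["H"] - cx["PYR"] * fx["H"]))
    out["GLUH"] = (p["GLUH", "A"] * ctx.tf["GLUH"]
                   * (ci["GLU"] * fi["H"] - cx["GLU"] * fx["H"]))

    # TCC: passive citrate(H)/malate and isocitrate(H)/malate exchange
    a_tcc = p["TCC", "A"] * ctx.tf["TCC"]
    out["CITMAL"] = a_tcc * (ci["CIT"] * hri * cx["MAL"]
                             - cx["CIT"] * hrx * ci["MAL"])
    out["ISOCMAL"] = a_tcc * (ci["ISOC"] * hri * cx["MAL"]
                              - cx["ISOC"] * hrx * ci["MAL"])

    # DCC: ternary-complex SUC/MAL against Pi (both electroneutral legs,
    # positive = dicarboxylate export / Pi import per Table direction)
    d = ((p["DCC", "K_dic"] + cx["SUC"] + cx["MAL"] + ci["SUC"] + ci["MAL"])
         * (p["DCC", "K_Pi"] + ci["Pi"] + cx["Pi"]))
    vd = p["DCC", "Vmax"] * ctx.tf["DCC"]
    out["SUCPI"] = vd * (cx["SUC"] * ci["Pi"] - ci["SUC"] * cx["Pi"]) / d
    out["MALPI"] = vd * (cx["MAL"] * ci["Pi"] - ci["MAL"] * cx["Pi"]) / d
    return out


# ---------------------------------------------------------------------------
# cation cycle
# ---------------------------------------------------------------------------

def cation_fluxes(ctx: RateContext) -> dict:
    """mHleak, mKleak, mKATP, mKHE, CaUNI, mNCE, mNHE.

    Leak fluxes are electrodiffusive (GHK) and vanish at the Nernst
    equilibrium.  The mKATP channel is inhibited by IMS-side MgATP
    (antagonized by MgADP); its endogenous inhibition coupling rho_endo is
    zeroed by diazoxide and its conductance by 5-hydroxydecanoate.  The
    mKHE rate scales with matrix volume (stretch activation), which is what
    makes it an effective volume controller.  The Ca2+ uniporter carries
    the nonlinear dpsi dependence with competitive Mg2+ inhibition; mNCE
    exchanges 3 Na+ per Ca2+ with a matrix-Ca2+ activation mechanism; mNHE
    carries a second-order proton regulation.
    """
    _check_domain(ctx)
    p = ctx.p
    fx, fi = ctx.fx, ctx.fi
    u = ctx.u
    eu = math.exp(min(u, 50.0))
    out = {}

    # proton and potassium leaks (GHK electrodiffusion, positive = influx)
    out["mHleak"] = (p["mHleak", "P_H"] * p["mHleak", "s_ref"]
                     * ctx.tf["mHleak"] * _xi(u)
                     * (fi["H"] - fx["H"] * eu))
    # K+ electrodiffusion uses a symmetric Eyring barrier (steeper
    # voltage dependence than the constant-field form); vanishes at the
    # Nernst equilibrium
    ep = math.exp(max(min(-0.5 * u, 25.0), -25.0))
    em = math.exp(max(min(0.5 * u, 25.0), -25.0))
    out["mKleak"] = (p["mKleak", "P_K"] * ctx.tf["mKleak"]
                     * (fi["K"] * ep - fx["K"] * em))

    # mKATP: MgATP-inhibited K+ channel
    mg_atp = ctx.ci.get("MgATP", 0.0)
    mg_adp = ctx.ci.get("MgADP", 0.0)
    rho = p["mKATP", "rho_endo"]
    block = (rho * (mg_atp / p["mKATP", "Ki_MgATP"])
             / (1.0 + mg_adp / p["mKATP", "Ki_MgADP"]))
    f_open = 1.0 / (1.0 + block)
    out["mKATP"] = (p["mKATP", "g"] * ctx.tf["mKATP"] * f_open
                    * (fi["K"] * ep - fx["K"] * em)
                    / p["mKATP", "K_ref"])

    # mKHE: volume-activated K+/H+ antiport, positive = K+ efflux.
    # Membrane stretch activates the exchanger steeply above a set-point
    # volume; the protocol-scoped Bose variant is instead a high-activity
    # rapid-equilibrium expression with no volume dependence.
    ratio = (fx["K"] * fi["H"]) / max(fi["K"] * fx["H"], 1e-300)
    if ctx.khe_bose:
        vact = p["general", "khe_bose_gain"]
    else:
        # activation proportional to swelling above the resting volume
        # (smoothed at the offset)
        z = (ctx.V_mtx - p["mKHE", "V0_act"]) / 0.05
        vact = (p["mKHE", "s_act"] * 0.05
                * math.log1p(math.exp(max(min(z, 50.0), -50.0))))
    out["mKHE"] = (p["mKHE", "V"] * ctx.tf["mKHE"] * vact * (ratio - 1.0))

    # CaUNI: GHK-type with competitive Mg2+ inhibition (z = 2)
    e2u = math.exp(min(2.0 * u, 50.0))
    kca = p["CaUNI", "K_Ca"]
    kmg = p["CaUNI", "Ki_Mg"]
    d = (kca * (1.0 + fi["Mg"] / kmg + fx["Mg"] / kmg)
         + fi["Ca"] + fx["Ca"])
    out["CaUNI"] = (p["CaUNI", "P_Ca"] * ctx.tf["CaUNI"] * _xi(2.0 * u)
                    * (fi["Ca"] - fx["Ca"] * e2u) / d)

    # mNCE: Ca_x + 3 Na_i -> Ca_i + 3 Na_x, net +1 charge in (forward)
    a = p["mNCE", "a_Ca"]
    act = ((1.0 + a * fx["Ca"] / (p["mNCE", "K_Caact"] + fx["Ca"]))
           / (1.0 + a))
    s_na_i = fi["Na"] ** 3 / (p["mNCE", "K_Na"] ** 3 + fi["Na"] ** 3)
    s_na_x = fx["Na"] ** 3 / (p["mNCE", "K_Na"] ** 3 + fx["Na"] ** 3)
    s_ca_x = fx["Ca"] / (p["mNCE", "K_Ca"] + fx["Ca"])
    s_ca_i = fi["Ca"] / (p["mNCE", "K_Ca"] + fi["Ca"])
    out["mNCE"] = (p["mNCE", "Vmax"] * ctx.tf["mNCE"] * act
                   * (s_ca_x * s_na_i - s_ca_i * s_na_x * eu))

    # mNHE: Na_x + H_i -> Na_i + H_x with Hill-2 proton regulation
    kh = p["mNHE", "K_Hreg"]
    nh = p["mNHE", "n_Hreg"]
    freg = fi["H"] ** nh / (fi["H"] ** nh + kh ** nh)
    kna = p["mNHE", "K_Na"]
    d = (kna + fx["Na"] + fi["Na"]) * (_HREF + fi["H"] + fx["H"])
    out["mNHE"] = (p["mNHE", "Vmax"] * ctx.tf["mNHE"] * freg
                   * (fx["Na"] * fi["H"] - fi["Na"] * fx["H"]) / d)
    return out


def all_fluxes(ctx: RateContext) -> dict:
    """Evaluate all 34 reaction/transport rates (nmol/min/mg)."""
    out = {}
    out.update(tca_fluxes(ctx))
    out.update(ets_fluxes(ctx))
    out.update(phosphorylation_fluxes(ctx))
    out.update(anion_transporter_fluxes(ctx))
    out.update(cation_fluxes(ctx))
    for name, v in out.items():
        if not math.isfinite(v):
            raise DomainError(f"non-finite flux for reaction {name}")
    return out
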