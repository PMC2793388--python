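"""Rate-law properties: Haldane consistency, regulation, saturation.

The central check builds, for every reversible expression, a state sitting
exactly on its thermodynamic equilibrium (recomputed in the test from the
shipped equilibrium constants, proton ratios and the membrane-potential
work terms, independently of the rate-law code paths) and asserts the flux
vanishes there.
"""

import math

import numpy as np
import pytest

from mitodyn.rates import (all_fluxes, tca_fluxes, ets_fluxes,
                           phosphorylation_fluxes, anion_transporter_fluxes,
                           cation_fluxes, FLUX_NAMES)
from mitodyn.thermo import KEQ_REF, R_GAS, FARADAY

from conftest import make_context

RT25 = R_GAS * 298.15
_HREF = 1e-7


def _u(ctx):
    return FARADAY * ctx.dpsi * 1e-3 / (R_GAS * (273.15 + ctx.T))


# ---------------------------------------------------------------------------
# Haldane: flux == 0 exactly at equilibrium, for every reversible law
# ---------------------------------------------------------------------------

def _equilibrate(rid, ctx):
    """Move one concentration so the reaction sits at equilibrium."""
    cx, ci, fx, fi = ctx.cx, ctx.ci, ctx.fx, ctx.fe
    fi = ctx.fi
    u = _u(ctx)
    eu = math.exp(u)
    hri = fi["H"] / _HREF
    hrx = fx["H"] / _HREF
    p = ctx.p
    rt = R_GAS * (273.15 + ctx.T)
    fpsi = FARADAY * ctx.dpsi * 1e-3
    if rid == "PDH":
        k = ctx.keq_app("PDH")
        cx["AcCoA"] = k * cx["PYR"] * cx["CoASH"] * cx["NAD"] / cx["NADH"]
    elif rid == "CS":
        cx["CIT"] = (ctx.keq_app("CS") * cx["OAA"] * cx["AcCoA"]
                     / cx["CoASH"])
    elif rid == "ACH":
        cx["ISOC"] = ctx.keq_app("ACH") * cx["CIT"]
    elif rid == "IDH":
        cx["aKG"] = (ctx.keq_app("IDH") * cx["ISOC"] * cx["NAD"]
                     / cx["NADH"])
    elif rid == "aKGDH":
        cx["SCoA"] = (ctx.keq_app("aKGDH") * cx["aKG"] * cx["CoASH"]
                      * cx["NAD"] / cx["NADH"])
    elif rid == "SCoAS":
        cx["SUC"] = (ctx.keq_app("SCoAS") * cx["SCoA"] * cx["GDP"]
                     * cx["Pi"] / (cx["GTP"] * cx["CoASH"]))
    elif rid == "SDH":
        cx["FUM"] = (ctx.keq_app("SDH") * cx["SUC"] * cx["UQ"]
                     / cx["UQH2"])
    elif rid == "FH":
        cx["MAL"] = ctx.keq_app("FH") * cx["FUM"]
    elif rid == "MDH":
        cx["OAA"] = (ctx.keq_app("MDH") * cx["MAL"] * cx["NAD"]
                     / cx["NADH"])
    elif rid == "NDK":
        cx["ATP"] = (ctx.keq_app("NDK") * cx["GTP"] * cx["ADP"]
                     / cx["GDP"])
    elif rid == "GOT":
        cx["OAA"] = (ctx.keq_app("GOT") * cx["ASP"] * cx["aKG"]
                     / cx["GLU"])
    elif rid == "AK":
        ci["ATP"] = ci["ADP"] ** 2 / (KEQ_REF["AK"][0] * ci["AMP"])
    elif rid == "HK":
        keq = KEQ_REF["HK"][0] * (_HREF / ctx.fe["H"]) ** KEQ_REF["HK"][1]
        ctx.ce["G6P"] = keq * ctx.ce["GLC"] * ctx.ce["ATP"] / ctx.ce["ADP"]
    elif rid == "CI":
        lnk = (-p["general", "dG0_CI"] + 4.0 * fpsi) / rt
        r1 = math.exp(4 * math.log(fi["H"]) - 5 * math.log(fx["H"]) - lnk)
        cx["NADH"] = cx["NAD"] * cx["UQH2"] * r1 / cx["UQ"]
    elif rid == "CIII":
        lnk = (-p["general", "dG0_CIII"] + 2.0 * fpsi) / rt
        r3 = math.exp(0.5 * (4 * math.log(fi["H"])
                             - 2 * math.log(fx["H"]) - lnk))
        ci["cred"] = (math.sqrt(cx["UQH2"] / cx["UQ"]) * ci["cox"] / r3)
    elif rid == "CIV":
        lnk = (-p["general", "dG0_CIV"] + 4.0 * fpsi) / rt
        o2 = p["general", "O2"]
        ln_ratio = 0.5 * (lnk - 2 * math.log(fi["H"])
                          + 4 * math.log(fx["H"]) + 0.5 * math.log(o2))
        ci["cred"] = ci["cox"] / math.exp(ln_ratio)
    elif rid == "F1FO":
        na = p["general", "n_F1FO"]
        lnk = (-p["general", "dG0_F1FO"] - na * fpsi) / rt
        r = math.exp((na - 1) * math.log(fx["H"])
                     - na * math.log(fi["H"]) - lnk)
        cx["Pi"] = cx["ATP"] * r / cx["ADP"]
    elif rid == "ANT":
        th = p["ANT", "theta"]
        e_f = math.exp(-th * u)
        e_r = math.exp((1 - th) * u)
        ctx.ligfree_x["ATP"] = (ctx.ligfree_i["ATP"] * e_r
                                * ctx.ligfree_x["ADP"]
                                / (ctx.ligfree_i["ADP"] * e_f))
    elif rid == "PIC":
        cx["Pi"] = ci["Pi"] * (hri / hrx) ** 2
    elif rid == "GAE":
        cx["ASP"] = (cx["GLU"] * hrx * ci["ASP"] * eu
                     / (ci["GLU"] * hri))
    elif rid == "OME":
        cx["aKG"] = ci["aKG"] * cx["MAL"] / ci["MAL"]
    elif rid == "PYRH":
        cx["PYR"] = ci["PYR"] * fi["H"] / fx["H"]
    elif rid == "GLUH":
        cx["GLU"] = ci["GLU"] * fi["H"] / fx["H"]
    elif rid == "CITMAL":
        cx["CIT"] = ci["CIT"] * hri * cx["MAL"] / (hrx * ci["MAL"])
    elif rid == "ISOCMAL":
        cx["ISOC"] = ci["ISOC"] * hri * cx["MAL"] / (hrx * ci["MAL"])
    elif rid == "SUCPI":
        ci["SUC"] = cx["SUC"] * ci["Pi"] / cx["Pi"]
    elif rid == "MALPI":
        ci["MAL"] = cx["MAL"] * ci["Pi"] / cx["Pi"]
    elif rid == "mHleak":
        fx["H"] = fi["H"] / eu
    elif rid == "mKHE":
        fx["K"] = fi["K"] * fx["H"] / fi["H"]
    elif rid in ("mKATP", "mKleak"):
        fx["K"] = fi["K"] / eu
    elif rid == "CaUNI":
        fx["Ca"] = fi["Ca"] / math.exp(2 * u)
    elif rid == "mNHE":
        fx["Na"] = fi["Na"] * fx["H"] / fi["H"]
    elif rid == "mNCE":
        return "numeric"
    else:
        raise KeyError(rid)
    return "analytic"


@pytest.mark.parametrize("rid", [r for r in FLUX_NAMES if r != "mNCE"])
def test_flux_vanishes_at_equilibrium(pset, rid):
    """Haldane consistency: the flux is zero exactly when the mass-action
    ratio (including proton and membrane-potential work terms) equals the
    apparent equilibrium constant."""
    ctx = make_context(pset)
    j0 = abs(all_fluxes(make_context(pset))[rid])
    kind = _equilibrate(rid, ctx)
    assert kind == "analytic"
    j_eq = all_fluxes(ctx)[rid]
    assert abs(j_eq) <= 1e-6 * (j0 + 1.0)


def test_mnce_reversal_point_exists(pset):
    """The Na+/Ca2+ exchanger reverses at a unique matrix-Na+ level: its
    flux changes sign continuously (numerical reversal-point check)."""
    def flux_at(na_x):
        ctx = make_context(pset, dpsi=0.0)
        ctx.fx["Na"] = na_x
        return cation_fluxes(ctx)["mNCE"]

    grid = np.logspace(-5, 0, 60)
    vals = np.array([flux_at(g) for g in grid])
    assert vals[0] > 0 and vals[-1] < 0
    assert np.sum(np.diff(np.sign(vals)) != 0) == 1


def test_flux_sign_follows_thermodynamic_driving(pset):
    """Displacing a near-equilibrium reaction to either side flips the
    flux sign accordingly (aconitase and the K+/H+ exchanger)."""
    for factor, sign in ((0.5, 1), (2.0, -1)):
        ctx = make_context(pset)
        ctx.cx["ISOC"] = factor * ctx.keq_app("ACH") * ctx.cx["CIT"]
        assert math.copysign(1, tca_fluxes(ctx)["ACH"]) == sign
        ctx = make_context(pset)
        ctx.fx["K"] = factor * ctx.fi["K"] * ctx.fx["H"] / ctx.fi["H"]
        assert math.copysign(1, cation_fluxes(ctx)["mKHE"]) == -sign


# ---------------------------------------------------------------------------
# TCA regulation
# ---------------------------------------------------------------------------

def test_pdh_approaches_printed_max_rate(pset):
    """Saturating substrates, zero products, full activation brings PDH
    close to its tabulated maximal rate."""
    ctx = make_context(pset)
    ctx.cx.update(PYR=5e-3, CoASH=5e-3, NAD=5e-3, AcCoA=0.0, NADH=0.0,
                  ATP=1e-9, ADP=5e-3)
    ctx.fx.update(Ca=1e-3, H=1e-9)
    j = tca_fluxes(ctx)["PDH"]
    assert 0.85 * 127 <= j <= 127.0 * 1.0001


def test_calcium_never_decreases_dehydrogenase_rates(pset):
    """Raising matrix free Ca2+ within the physiological range never
    decreases PDH, IDH or aKGDH."""
    ca_grid = [1e-8, 1e-7, 5e-7, 2e-6, 1e-5]
    rates = {"PDH": [], "IDH": [], "aKGDH": []}
    for ca in ca_grid:
        ctx = make_context(pset)
        ctx.fx["Ca"] = ca
        j = tca_fluxes(ctx)
        for rid in rates:
            rates[rid].append(j[rid])
    for rid, vals in rates.items():
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:])), rid


def test_mdh_pi_activation_is_saturable_increase(pset):
    vals = []
    for pi in (1e-4, 2e-3, 2e-2):
        ctx = make_context(pset)
        ctx.cx.update(Pi=pi, OAA=0.0, NADH=1e-5)   # far from equilibrium
        vals.append(tca_fluxes(ctx)["MDH"])
    assert vals[0] < vals[1] < vals[2]
    # saturable: the second step gains less (relative) than the first
    assert vals[2] / vals[1] < vals[1] / vals[0]


def test_domain_error_on_negative_concentration(pset):
    ctx = make_context(pset)
    ctx.cx["PYR"] = -1e-6
    with pytest.raises(ValueError):
        tca_fluxes(ctx)


# ---------------------------------------------------------------------------
# electron transport
# ---------------------------------------------------------------------------

def test_fully_oxidized_chain_zero_fluxes(pset):
    ctx = make_context(pset)
    ctx.cx.update(NADH=0.0, UQH2=0.0)
    ctx.ci.update(cred=0.0)
    j = ets_fluxes(ctx)
    assert j["CI"] <= 0 and j["CIII"] <= 0 and j["CIV"] <= 0
    ctx.cx.update(NAD=0.0, UQ=0.0)
    ctx.ci.update(cox=0.0)
    j = ets_fluxes(ctx)
    assert j["CI"] == 0 and j["CIII"] == 0 and abs(j["CIV"]) == 0


def test_pumping_decreases_with_polarization(pset):
    """Each proton-pumping flux decreases monotonically in |dpsi| at fixed
    redox state."""
    flux = {r: [] for r in ("CI", "CIII", "CIV")}
    for dpsi in (0.0, -60.0, -120.0, -180.0):
        ctx = make_context(pset, dpsi=dpsi)
        j = ets_fluxes(ctx)
        for r in flux:
            flux[r].append(j[r])
    for r, vals in flux.items():
        assert all(b < a for a, b in zip(vals, vals[1:])), r


def test_ciii_pi_activation(pset):
    vals = []
    for pi in (1e-4, 2e-3, 1e-2):
        ctx = make_context(pset)
        ctx.cx["Pi"] = pi
        vals.append(ets_fluxes(ctx)["CIII"])
    assert vals[0] < vals[1] < vals[2]


def test_civ_activity_scales_linearly(pset):
    ctx = make_context(pset)
    j1 = ets_fluxes(ctx)["CIV"]
    ps2 = pset.copy()
    ps2["CIV", "V"] = 2 * pset["CIV", "V"]
    ctx2 = make_context(ps2)
    assert ets_fluxes(ctx2)["CIV"] == pytest.approx(2 * j1, rel=1e-12)


def test_o2_depletion_zeroes_respiration(pset):
    ctx = make_context(pset, o2_depleted=True)
    j = ets_fluxes(ctx)
    assert j == {"CI": 0.0, "CIII": 0.0, "CIV": 0.0}


def test_proton_pumping_stoichiometry_ledger(pset):
    """10 charges per NADH oxidized: the charge coefficients of CI, CIII
    and CIV sum to the textbook proton-pumping stoichiometry, and the
    per-complex proton ledgers balance (matrix loss + IMS gain = pumped +
    scalar chemistry protons)."""
    from mitodyn.model import CHARGE_COEFF, STOICH
    assert CHARGE_COEFF["CI"] + CHARGE_COEFF["CIII"] + CHARGE_COEFF["CIV"] \
        == -10.0
    # per-complex hydrogen bookkeeping over one turnover
    assert STOICH["CI"]["H_x"] == -5 and STOICH["CI"]["H_i"] == 4
    assert STOICH["CIII"]["H_x"] == -2 and STOICH["CIII"]["H_i"] == 4
    assert STOICH["CIV"]["H_x"] == -4 and STOICH["CIV"]["H_i"] == 2
    # net protons consumed by the chemistry per NADH -> 1/2 O2 equals 1
    net = sum(STOICH[c]["H_x"] + STOICH[c]["H_i"]
              for c in ("CI", "CIII", "CIV"))
    assert net == -1


# ---------------------------------------------------------------------------
# phosphorylation subsystem
# ---------------------------------------------------------------------------

def test_ant_symmetric_zero(pset):
    """Identical nucleotide ratios on both sides at dpsi = 0 give no ANT
    flux."""
    ctx = make_context(pset, dpsi=0.0)
    ctx.ligfree_x.update(ATP=1e-3, ADP=2e-3)
    ctx.ligfree_i.update(ATP=1e-4, ADP=2e-4)
    assert phosphorylation_fluxes(ctx)["ANT"] == pytest.approx(0.0,
                                                               abs=1e-12)


def test_ant_bounded_by_printed_max_rate(pset):
    rng = np.random.default_rng(2)
    vmax = pset["ANT", "Vmax"]
    for _ in range(50):
        ctx = make_context(pset, dpsi=float(rng.uniform(-200, 0)))
        ctx.ligfree_x.update(ATP=float(rng.uniform(0, 1e-2)),
                             ADP=float(rng.uniform(0, 1e-2)))
        ctx.ligfree_i.update(ATP=float(rng.uniform(0, 1e-2)),
                             ADP=float(rng.uniform(0, 1e-2)))
        assert abs(phosphorylation_fluxes(ctx)["ANT"]) <= vmax * 1.0001


def test_f1fo_reverses_when_pmf_insufficient(pset):
    """With a collapsed potential and a high matrix phosphorylation
    potential the same F1FO expression hydrolyzes ATP."""
    ctx = make_context(pset, dpsi=-180.0)
    j_syn = phosphorylation_fluxes(ctx)["F1FO"]
    assert j_syn > 0
    ctx = make_context(pset, dpsi=0.0)
    ctx.cx.update(ATP=8e-3, ADP=2e-4, Pi=5e-4)
    j_hyd = phosphorylation_fluxes(ctx)["F1FO"]
    assert j_hyd < 0


def test_carrier_saturation_bounds(pset):
    """|J| never exceeds the temperature-corrected tabulated max rate for
    the saturable carriers (OME, DCC legs, PIC, mNCE; GAE unstimulated)."""
    rng = np.random.default_rng(5)
    for _ in range(40):
        ctx = make_context(pset, dpsi=float(rng.uniform(-200, 0)))
        ctx.fe["Ca"] = 0.0
        for d in (ctx.cx, ctx.ci):
            for k in ("aKG", "MAL", "SUC", "Pi", "GLU", "ASP"):
                d[k] = float(rng.uniform(0, 2e-2))
        j = anion_transporter_fluxes(ctx)
        assert abs(j["OME"]) <= pset["OME", "Vf"] * 1.0001
        assert abs(j["SUCPI"]) <= pset["DCC", "Vmax"] * 1.0001
        assert abs(j["MALPI"]) <= pset["DCC", "Vmax"] * 1.0001
        assert abs(j["GAE"]) <= pset["GAE", "V0"] * 1.0001
        jp = phosphorylation_fluxes(ctx)
        assert abs(jp["PIC"]) <= pset["PIC", "Vmax"] * 1.0001
        jc = cation_fluxes(ctx)
        assert abs(jc["mNCE"]) <= pset["mNCE", "Vmax"] * 1.0001


# ---------------------------------------------------------------------------
# anion transporters
# ---------------------------------------------------------------------------

def test_tcc_symmetric_zero(pset):
    ctx = make_context(pset)
    ctx.fx["H"] = ctx.fi["H"]
    ctx.cx.update(CIT=3e-4, MAL=1e-3)
    ctx.ci.update(CIT=3e-4, MAL=1e-3)
    assert anion_transporter_fluxes(ctx)["CITMAL"] == pytest.approx(
        0.0, abs=1e-12)


def test_gae_is_electrogenic_and_calcium_activated(pset):
    """GAE depends on dpsi (electrogenic) and is stimulated by external
    calcium with its tabulated activation amplitude."""
    ctx0 = make_context(pset, dpsi=0.0)
    ctx1 = make_context(pset, dpsi=-160.0)
    j0 = anion_transporter_fluxes(ctx0)["GAE"]
    j1 = anion_transporter_fluxes(ctx1)["GAE"]
    assert j1 != pytest.approx(j0, rel=1e-6)
    lo = make_context(pset)
    lo.fe["Ca"] = 0.0
    hi = make_context(pset)
    hi.fe["Ca"] = 1e-3
    jlo = anion_transporter_fluxes(lo)["GAE"]
    jhi = anion_transporter_fluxes(hi)["GAE"]
    assert jhi == pytest.approx(jlo * (1 + pset["GAE", "a_Ca"]), rel=1e-3)


def test_dpsi_independent_carriers(pset):
    """DCC, TCC, PYRH and GLUH do not sense the membrane potential."""
    a = make_context(pset, dpsi=0.0)
    b = make_context(pset, dpsi=-180.0)
    ja = anion_transporter_fluxes(a)
    jb = anion_transporter_fluxes(b)
    for rid in ("SUCPI", "MALPI", "CITMAL", "ISOCMAL", "PYRH", "GLUH"):
        assert ja[rid] == pytest.approx(jb[rid], rel=1e-12)


# ---------------------------------------------------------------------------
# cation cycle
# ---------------------------------------------------------------------------

def test_cauni_zero_at_symmetric_calcium(pset):
    ctx = make_context(pset, dpsi=0.0)
    ctx.fi["Ca"] = ctx.fx["Ca"] = 5e-7
    assert cation_fluxes(ctx)["CaUNI"] == pytest.approx(0.0, abs=1e-12)


def test_cauni_magnesium_competitive_shift(pset):
    """Competitive Mg2+ raises the apparent Ca2+ half-saturation of the
    uniporter (numerical titration oracle)."""
    def half_sat(mg):
        cas = np.logspace(-8, -2, 200)
        js = []
        for ca in cas:
            ctx = make_context(pset, dpsi=-120.0)
            ctx.fi["Ca"] = ca
            ctx.fx["Ca"] = 1e-9
            ctx.fi["Mg"] = ctx.fx["Mg"] = mg
            js.append(cation_fluxes(ctx)["CaUNI"])
        js = np.array(js)
        return cas[int(np.argmin(np.abs(js - js.max() / 2)))]

    assert half_sat(2e-3) > 5 * half_sat(0.0)


def test_mkatp_nucleotide_gating(pset):
    """mKATP approaches its unblocked maximum as MgATP -> 0, is shut by
    saturating MgATP, and MgADP antagonizes the block; zeroing the
    endogenous coupling (diazoxide) removes the block entirely."""
    def flux(mgatp, mgadp, rho=1.0):
        ps = pset.copy()
        ps["mKATP", "rho_endo"] = rho
        ctx = make_context(ps, dpsi=-150.0)
        ctx.ci["MgATP"] = mgatp
        ctx.ci["MgADP"] = mgadp
        return cation_fluxes(ctx)["mKATP"]

    open_max = flux(0.0, 0.0)
    assert open_max > 0
    assert flux(1e-4, 0.0) <= 1e-3 * open_max
    assert flux(1e-4, 1e-3) > flux(1e-4, 0.0)
    assert flux(1e-4, 0.0, rho=0.0) == pytest.approx(open_max, rel=1e-12)


def test_mkhe_scales_with_matrix_volume(pset):
    vols = (0.7, 1.2, 2.0)
    js = []
    for v in vols:
        ctx = make_context(pset, V_mtx=v)
        ctx.fx["K"] = 2 * ctx.fi["K"]   # clear outward driving
        js.append(cation_fluxes(ctx)["mKHE"])
    assert js[0] < js[1] < js[2]


def test_bose_variant_mkhe_is_rapid_equilibrium(pset):
    ctx = make_context(pset, khe_bose=True)
    ctx.fx["K"] = 1.05 * ctx.fi["K"] * ctx.fx["H"] / ctx.fi["H"]
    j_fast = cation_fluxes(ctx)["mKHE"]
    ctx2 = make_context(pset, khe_bose=False)
    ctx2.fx["K"] = ctx.fx["K"]
    ctx2.fx["H"] = ctx.fx["H"]
    j_slow = cation_fluxes(ctx2)["mKHE"]
    assert j_fast > 100 * abs(j_slow)


def test_fluxes_continuous_in_dpsi(pset):
    """Continuity in the membrane potential: the largest inter-sample jump
    of every flux shrinks proportionally when the sweep is refined (a
    discontinuity would keep a constant-size jump)."""
    def max_jumps(n):
        grid = np.linspace(-200.0, 20.0, n)
        vals = []
        for dpsi in grid:
            j = all_fluxes(make_context(pset, dpsi=float(dpsi)))
            vec = np.array([j[r] for r in FLUX_NAMES])
            assert np.all(np.isfinite(vec))
            vals.append(vec)
        return np.max(np.abs(np.diff(np.asarray(vals), axis=0)), axis=0)

    coarse = max_jumps(45)
    fine = max_jumps(441)
    scale = np.maximum(coarse, 1e-9)
    assert np.all(fine / scale < 0.35)
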