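"""Rate-law unit and property tests.

Every mechanism is checked against an independently hand-coded oracle (a
plain transcription of the corresponding rate equation, no shared code),
against closed-form special values, and against the printed limiting rates
at saturating substrates.
"""

import numpy as np
import pytest

from tcaflux.rate_laws import (CONSTANT_FLUX_GUARD, ConfigurationError,
                               KineticParameterSet, MECHANISMS, evaluate,
                               rate_bi_bi, rate_bi_bi_2V, rate_constant_flux,
                               rate_gdh, rate_gr, rate_idh_nadp,
                               rate_mwc_idh_nad, rate_random_bi_bi,
                               rate_ter_bi, rate_ter_ter, rate_uni_uni,
                               rate_uni_uni_2V)

from conftest import random_positive_params


# ---------------------------------------------------------------------------
# oracles: plain transcriptions, deliberately not refactored
# ---------------------------------------------------------------------------

def oracle_ter_bi(p, A, B, C, P, Q):
    Ka = p.km["Ka"]; Kb = p.km["Kb"]; Kc = p.km["Kc"]
    Kp = p.km["Kp"]; Kq = p.km["Kq"]
    top = p.vmaxf / (Ka * Kb * Kc) * (A * B * C - P * Q / p.keq)
    bottom = (1 + A / Ka + (A * B) / (Ka * Kb)
              + (A * B * C) / (Ka * Kb * Kc)
              + (P * Q) / (Kp * Kq) + Q / Kq)
    return top / bottom


def oracle_random_bi_bi(p, A, B, P, Q):
    Ka = p.km["Ka"]; Kb = p.km["Kb"]; Kp = p.km["Kp"]; Kq = p.km["Kq"]
    top = p.vmaxf / (Ka * Kb) * (A * B - P * Q / p.keq)
    bottom = (1 + A / Ka + B / Kb + (A * B) / (Ka * Kb) + P / Kp + Q / Kq
              + (P * Q) / (Kp * Kq) + (A * Q) / (Ka * Kq)
              + (P * B) / (Kp * Kb))
    return top / bottom


def oracle_uni_uni(p, A, P):
    Ka = p.km["Ka"]; Kp = p.km["Kp"]
    return (p.vmaxf / Ka * (A - P / p.keq)
            / (1 + A / Ka + P / Kp))


def oracle_mwc_idh(p, NAD, Iso, OXO, NADH):
    Ka = p.km["Ka"]; Kb = p.km["Kb"]; Kp = p.km["Kp"]; Kq = p.km["Kq"]
    a = NAD / Ka
    if "Ki_NADH_vs_NAD" in p.ki:
        a = (NAD / Ka) / (1 + NADH / p.ki["Ki_NADH_vs_NAD"])
    nad_part = a / (1 + a)
    b = Iso / Kb
    mwc_top = b * (1 + b) ** (p.n - 1)
    mwc_bottom = (p.L * (1 + NADH / p.ki["Ki_NADH_vs_Iso"]) ** p.n
                  + (1 + b) ** p.n)
    reverse = ((OXO * NADH) / (Kp * Kq * p.keq)
               / (1 + OXO / Kp + NADH / Kq + (OXO * NADH) / (Kp * Kq)))
    return p.vmaxf * (nad_part * mwc_top / mwc_bottom - reverse)


def oracle_idh_nadp(p, NADP, Iso, OXO, NADPH, GSH, NAD):
    Ka = p.km["Ka"]; Kb = p.km["Kb"]; Kp = p.km["Kp"]; Kq = p.km["Kq"]
    top = p.vmaxf / (Ka * Kb) * (NADP * Iso - OXO * NADPH / p.keq)
    bottom = (1 + NADP / Ka + (NADP * GSH) / (Ka * p.ki["Ki_GSH"])
              + (NADP * Iso) / (Ka * Kb)
              + (NADPH * Iso) / (Kq * Kb) + (NADPH * OXO) / (Kq * Kp)
              + NADPH / Kq + NAD / p.ki["Ki_NAD"])
    return top / bottom


def oracle_ter_ter(p, A, B, C, P, Q, R):
    Ka = p.km["Ka"]; Kb = p.km["Kb"]; Kc = p.km["Kc"]
    Kp = p.km["Kp"]; Kq = p.km["Kq"]; Kr = p.km["Kr"]
    top = p.vmaxf / (Ka * Kb * Kc) * (A * B * C - P * Q * R / p.keq)
    bottom = (1 + A / Ka + (A * B) / (Ka * Kb)
              + (A * B * C) / (Ka * Kb * Kc)
              + (P * Q * R) / (Kp * Kq * Kr) + (Q * R) / (Kq * Kr) + R / Kr)
    return top / bottom


def oracle_bi_bi(p, A, B, P, Q):
    Ka = p.km["Ka"]; Kb = p.km["Kb"]; Kp = p.km["Kp"]; Kq = p.km["Kq"]
    top = p.vmaxf / (Ka * Kb) * (A * B - P * Q / p.keq)
    bottom = (1 + A / Ka + (A * B) / (Ka * Kb) + (P * Q) / (Kp * Kq)
              + Q / Kq)
    return top / bottom


def oracle_uni_uni_2V(p, A, P):
    Ka = p.km["Ka"]; Kp = p.km["Kp"]
    return ((p.vmaxf * A / Ka - p.vmaxr * P / Kp)
            / (1 + A / Ka + P / Kp))


def oracle_bi_bi_2V(p, A, B, P, Q):
    Ka = p.km["Ka"]; Kb = p.km["Kb"]; Kp = p.km["Kp"]; Kq = p.km["Kq"]
    top = (p.vmaxf * A * B / (Ka * Kb) - p.vmaxr * P * Q / (Kp * Kq))
    bottom = (1 + A / Ka + (A * B) / (Ka * Kb) + (P * Q) / (Kp * Kq)
              + Q / Kq)
    return top / bottom


def oracle_gdh(p, NADP, Glu, OXO, NADPH, NH4, GTP, ADP):
    Ka = p.km["Ka"]; Kb = p.km["Kb"]; Kp = p.km["Kp"]
    Kq = p.km["Kq"]; Kr = p.km["Kr"]
    forward = ((NADP * Glu) / (Ka * Kb)
               / (1 + NADP / Ka + (NADP * Glu) / (Ka * Kb)))
    reverse = ((OXO * NADPH) / (Kp * Kq)
               / (1 + OXO / Kp + (OXO * NADPH) / (Kp * Kq)))
    rho = NH4 / Kr
    L_eff = (p.L * (1 + GTP / p.ki["Ki_GTP"]) ** p.n
             / (1 + ADP / p.ka_act["Ka_ADP"]))
    gate = rho * (1 + rho) ** (p.n - 1) / (L_eff + (1 + rho) ** p.n)
    return p.vmaxf * forward - p.vmaxr * reverse * gate


def oracle_gr(p, NADPH, GSSG, NADP, GSH):
    Ka = p.km["Ka"]; Kb = p.km["Kb"]; Kp = p.km["Kp"]
    Kq = p.km["Kq"]; Kr = p.km["Kr"]
    top = p.vmaxf / (Ka * Kb) * (NADPH * GSSG - NADP * GSH * GSH / p.keq)
    bottom = (1 + NADPH / Ka + (NADPH * GSSG) / (Ka * Kb)
              + (NADP * GSH * GSH) / (Kp * Kq * Kr)
              + (GSH * GSH) / (Kq * Kr) + GSH / Kq + GSH / Kr)
    return top / bottom


ORACLES = {
    "ter_bi": oracle_ter_bi,
    "random_bi_bi": oracle_random_bi_bi,
    "uni_uni": oracle_uni_uni,
    "mwc_idh": oracle_mwc_idh,
    "bi_bi_inhib": oracle_idh_nadp,
    "ter_ter": oracle_ter_ter,
    "bi_bi": oracle_bi_bi,
    "uni_uni_2V": oracle_uni_uni_2V,
    "bi_bi_2V": oracle_bi_bi_2V,
    "gdh_mwc": oracle_gdh,
    "gr_bi_ter": oracle_gr,
    "constant_flux": lambda p, S: p.vmaxf * S / (S + CONSTANT_FLUX_GUARD),
}


def _params(mechanism, **kwargs):
    defaults = dict(enzyme_id="test", mechanism=mechanism)
    defaults.update(kwargs)
    return KineticParameterSet(**defaults)


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mechanism", sorted(MECHANISMS))
def test_oracle_equivalence_random_points(mechanism):
    rng = np.random.default_rng(hash(mechanism) % 2 ** 31)
    info = MECHANISMS[mechanism]
    oracle = ORACLES[mechanism]
    for _ in range(1000):
        p = random_positive_params(rng, mechanism)
        concs = np.exp(rng.uniform(np.log(1e-4), np.log(10.0),
                                   size=len(info.roles)))
        expected = oracle(p, *concs)
        got = info.fn(p, *concs)
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-300)


# ---------------------------------------------------------------------------
# closed-form and printed-value examples
# ---------------------------------------------------------------------------

class TestTerBi:
    def test_zero_at_zero(self):
        p = _params("ter_bi", vmaxf=10, keq=5,
                    km=dict(Ka=1, Kb=1, Kc=1, Kp=1, Kq=1))
        assert rate_ter_bi(p, 0, 0, 0, 0, 0) == 0

    def test_quarter_vmax_at_km(self):
        p = _params("ter_bi", vmaxf=8.0, keq=5,
                    km=dict(Ka=0.3, Kb=0.7, Kc=1.1, Kp=1, Kq=1))
        v = rate_ter_bi(p, 0.3, 0.7, 1.1, 0, 0)
        assert v == pytest.approx(8.0 / 4.0, rel=1e-12)

    def test_pdh_saturation(self):
        # printed HepM pyruvate-dehydrogenase constants
        p = _params("ter_bi", vmaxf=26.0, keq=1e9,
                    km=dict(Ka=0.21, Kb=0.014, Kc=0.34, Kp=0.04, Kq=0.03))
        v = rate_ter_bi(p, 210.0, 14.0, 340.0, 0, 0)
        assert v == pytest.approx(26.0, rel=0.01)

    def test_sign_follows_displacement(self):
        p = _params("ter_bi", vmaxf=5, keq=2.0,
                    km=dict(Ka=1, Kb=1, Kc=1, Kp=1, Kq=1))
        assert rate_ter_bi(p, 1, 1, 1, 3, 3) < 0
        assert rate_ter_bi(p, 2, 2, 2, 1, 1) > 0


class TestRandomBiBi:
    def test_quarter_vmax(self):
        p = _params("random_bi_bi", vmaxf=12.0, keq=10,
                    km=dict(Ka=0.4, Kb=0.9, Kp=1, Kq=2))
        assert rate_random_bi_bi(p, 0.4, 0.9, 0, 0) == pytest.approx(
            3.0, rel=1e-12)

    def test_equilibrium_zero(self):
        p = _params("random_bi_bi", vmaxf=12.0, keq=4.0,
                    km=dict(Ka=0.4, Kb=0.9, Kp=1, Kq=2))
        # A*B*Keq == P*Q
        assert rate_random_bi_bi(p, 1.0, 0.5, 1.0, 2.0) == pytest.approx(
            0.0, abs=1e-12)

    def test_cs_saturation(self):
        p = _params("random_bi_bi", vmaxf=1260.0, keq=1e9,
                    km=dict(Ka=0.003, Kb=0.011, Kp=0.1, Kq=1.0))
        v = rate_random_bi_bi(p, 3.0, 11.0, 0, 0)
        assert v == pytest.approx(1260.0, rel=0.01)


class TestUniUni:
    def test_zero_and_equilibrium(self):
        p = _params("uni_uni", vmaxf=7, keq=3.0, km=dict(Ka=0.5, Kp=0.8))
        assert rate_uni_uni(p, 0, 0) == 0
        assert rate_uni_uni(p, 1.0, 3.0) == pytest.approx(0.0, abs=1e-12)

    def test_aco_saturation(self):
        p = _params("uni_uni", vmaxf=173.0, keq=1e9,
                    km=dict(Ka=0.22, Kp=0.12))
        assert rate_uni_uni(p, 220.0, 0) == pytest.approx(173.0, rel=0.01)


class TestMwcIdh:
    P = dict(vmaxf=51.0, keq=545.0, km=dict(Ka=0.25, Kb=5.7, Kp=1.0,
                                            Kq=0.03),
             ki={"Ki_NADH_vs_Iso": 0.04, "Ki_NADH_vs_NAD": 0.08},
             n=2.33, L=0.64)

    def test_zero_substrate(self):
        p = _params("mwc_idh", **self.P)
        assert rate_mwc_idh_nad(p, 1.0, 0, 0, 0) == 0

    def test_limit_L_to_zero_saturating(self):
        kwargs = dict(self.P, L=1e-12)
        p = _params("mwc_idh", **kwargs)
        v = rate_mwc_idh_nad(p, 250.0, 5700.0, 0, 0)
        assert v == pytest.approx(51.0, rel=0.01)

    def test_strictly_decreasing_in_nadh(self):
        p = _params("mwc_idh", **self.P)
        scan = [rate_mwc_idh_nad(p, 1.0, 2.0, 0.1, nadh)
                for nadh in np.linspace(0, 0.1, 50)]
        assert np.all(np.diff(scan) < 0)

    def test_bounded_by_vmaxf(self):
        p = _params("mwc_idh", **self.P)
        rng = np.random.default_rng(0)
        for _ in range(200):
            c = np.exp(rng.uniform(-5, 3, size=4))
            assert abs(rate_mwc_idh_nad(p, *c)) <= 51.0 * (1 + 1e-9)

    def test_invalid_allosteric_constants(self):
        with pytest.raises(ConfigurationError):
            _params("mwc_idh", **dict(self.P, n=0.5))


class TestIdhNadp:
    P = dict(vmaxf=587.0, keq=545.0,
             km=dict(Ka=0.078, Kb=0.046, Kp=1.0, Kq=0.03),
             ki={"Ki_GSH": 3.5, "Ki_NAD": 0.5})

    def test_zero_substrate(self):
        p = _params("bi_bi_inhib", **self.P)
        assert rate_idh_nadp(p, 1.0, 0, 0, 0, 0, 0) == 0

    def test_saturation(self):
        p = _params("bi_bi_inhib", **self.P)
        v = rate_idh_nadp(p, 78.0, 46.0, 0, 0, 0, 0)
        assert v == pytest.approx(587.0, rel=0.01)

    def test_gsh_drives_rate_to_zero(self):
        p = _params("bi_bi_inhib", **self.P)
        v0 = rate_idh_nadp(p, 0.3, 0.1, 0, 0, 0.0, 0)
        vals = [rate_idh_nadp(p, 0.3, 0.1, 0, 0, gsh, 0)
                for gsh in (1.0, 10.0, 100.0, 1e4)]
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 1e-2 * v0

    def test_nad_never_increases_rate(self):
        p = _params("bi_bi_inhib", **self.P)
        vals = [rate_idh_nadp(p, 0.3, 0.1, 0.05, 0.5, 2.0, nad)
                for nad in (0, 1.0, 5.0, 20.0)]
        assert np.all(np.diff(vals) <= 0)


class TestTerTer:
    P = dict(vmaxf=40.0, keq=3.7,
             km=dict(Ka=0.05, Kb=0.25, Kc=2.5, Kp=0.6, Kq=0.07, Kr=2.0))

    def test_zero(self):
        p = _params("ter_ter", **self.P)
        assert rate_ter_ter(p, 0, 0, 0, 0, 0, 0) == 0

    def test_quarter_vmax(self):
        p = _params("ter_ter", **self.P)
        v = rate_ter_ter(p, 0.05, 0.25, 2.5, 0, 0, 0)
        assert v == pytest.approx(10.0, rel=1e-12)

    def test_equilibrium_zero(self):
        p = _params("ter_ter", **self.P)
        # choose products such that P*Q*R = A*B*C*Keq
        abc = 0.3 * 0.4 * 0.5
        v = rate_ter_ter(p, 0.3, 0.4, 0.5, abc * 3.7, 1.0, 1.0)
        assert v == pytest.approx(0.0, abs=1e-12)


class TestBiBi:
    def test_third_vmax(self):
        p = _params("bi_bi", vmaxf=9.0, keq=30.0,
                    km=dict(Ka=0.07, Kb=0.1, Kp=0.15, Kq=0.6))
        assert rate_bi_bi(p, 0.07, 0.1, 0, 0) == pytest.approx(
            3.0, rel=1e-12)

    def test_me_saturation(self):
        p = _params("bi_bi", vmaxf=70.0, keq=1e9,
                    km=dict(Ka=0.5, Kb=1.4, Kp=5.0, Kq=0.05))
        assert rate_bi_bi(p, 500.0, 1400.0, 0, 0) == pytest.approx(
            70.0, rel=0.01)


class TestTwoVmaxForms:
    def test_uni_uni_2V_pseudo_equilibrium(self):
        p = _params("uni_uni_2V", vmaxf=10.0, vmaxr=4.0,
                    km=dict(Ka=0.5, Kp=0.8))
        # Vmaxf*A/Ka == Vmaxr*P/Kp
        A = 0.2
        P = (10.0 * A / 0.5) * 0.8 / 4.0
        assert rate_uni_uni_2V(p, A, P) == pytest.approx(0.0, abs=1e-12)

    def test_fh_saturation(self):
        p = _params("uni_uni_2V", vmaxf=3356.0, vmaxr=340.0,
                    km=dict(Ka=1.0, Kp=0.4))
        assert rate_uni_uni_2V(p, 1000.0, 0) == pytest.approx(
            3356.0, rel=0.01)

    def test_mdh_reverse_saturation(self):
        p = _params("bi_bi_2V", vmaxf=269.0, vmaxr=2074.0,
                    km=dict(Ka=0.11, Kb=0.45, Kp=0.007, Kq=0.017))
        v = rate_bi_bi_2V(p, 0, 0, 7.0, 17.0)
        assert v == pytest.approx(-2074.0, rel=0.01)

    def test_bi_bi_2V_balanced_numerator(self):
        p = _params("bi_bi_2V", vmaxf=8.0, vmaxr=2.0,
                    km=dict(Ka=1.0, Kb=1.0, Kp=1.0, Kq=1.0))
        # 8*A*B == 2*P*Q
        assert rate_bi_bi_2V(p, 0.5, 0.5, 1.0, 1.0) == pytest.approx(
            0.0, abs=1e-12)


class TestGdh:
    P = dict(vmaxf=2.0, vmaxr=19.0,
             km=dict(Ka=0.53, Kb=8.8, Kp=0.08, Kq=0.04, Kr=1.1),
             L=1.0, n=2.0, ki={"Ki_GTP": 0.2}, ka_act={"Ka_ADP": 1.0})

    def test_zero(self):
        p = _params("gdh_mwc", **self.P)
        assert rate_gdh(p, 0, 0, 0, 0, 0, 0, 0) == 0

    def test_forward_saturation(self):
        p = _params("gdh_mwc", **self.P)
        v = rate_gdh(p, 530.0, 8800.0, 0, 0, 1.0, 0, 0)
        assert v == pytest.approx(2.0, rel=0.01)

    def test_gtp_lowers_and_adp_raises_reverse(self):
        p = _params("gdh_mwc", **self.P)
        args = dict(NADP=0, Glu=0, OXO=0.5, NADPH=0.5, NH4=2.0)
        base = rate_gdh(p, *args.values(), 0.0, 0.0)
        with_gtp = rate_gdh(p, *args.values(), 1.0, 0.0)
        with_adp = rate_gdh(p, *args.values(), 0.0, 5.0)
        assert abs(with_gtp) < abs(base)
        assert abs(with_adp) > abs(base)

    def test_adp_limit_removes_gate(self):
        p = _params("gdh_mwc", **self.P)
        rho = 2.0 / 1.1
        hill = rho * (1 + rho) ** (p.n - 1) / (1 + rho) ** p.n
        v = rate_gdh(p, 0, 0, 0.5, 0.5, 2.0, 0.0, 1e9)
        reverse = (0.5 * 0.5 / (0.08 * 0.04)
                   / (1 + 0.5 / 0.08 + 0.5 * 0.5 / (0.08 * 0.04)))
        assert v == pytest.approx(-19.0 * reverse * hill, rel=1e-4)


class TestGr:
    P = dict(vmaxf=40.0, keq=5e5,
             km=dict(Ka=0.01, Kb=0.06, Kp=0.02, Kq=20.0, Kr=20.0))

    def test_zero_and_equilibrium(self):
        p = _params("gr_bi_ter", **self.P)
        assert rate_gr(p, 0, 0, 0, 0) == 0
        # A*B*Keq == P*Q*R with Q=R=GSH
        gsh = 10.0
        nadp = 0.02 * 0.5 * 5e5 / gsh ** 2
        assert rate_gr(p, 0.02, 0.5, nadp, gsh) == pytest.approx(
            0.0, abs=1e-10)

    def test_third_vmax_at_km(self):
        # denominator 1 + A/Ka + AB/(KaKb) = 3 at A=Ka, B=Kb, products 0
        p = _params("gr_bi_ter", **self.P)
        v = rate_gr(p, 0.01, 0.06, 0, 0)
        assert v == pytest.approx(40.0 / 3.0, rel=1e-12)


class TestConstantFlux:
    def test_guard(self):
        p = _params("constant_flux", vmaxf=100.0)
        assert rate_constant_flux(p, 0.0) == 0
        assert rate_constant_flux(p, 1.0) == pytest.approx(100.0, abs=1e-4)
        assert rate_constant_flux(p, CONSTANT_FLUX_GUARD) == pytest.approx(
            50.0, rel=1e-12)


# ---------------------------------------------------------------------------
# generic properties
# ---------------------------------------------------------------------------

EQUILIBRIUM_CASES = ["ter_bi", "random_bi_bi", "uni_uni", "ter_ter",
                     "bi_bi", "gr_bi_ter"]


@pytest.mark.parametrize("mechanism", EQUILIBRIUM_CASES)
def test_equilibrium_root(mechanism):
    """Reversible laws vanish exactly at the mass-action equilibrium."""
    rng = np.random.default_rng(7)
    info = MECHANISMS[mechanism]
    n_sub = {"ter_bi": 3, "random_bi_bi": 2, "uni_uni": 1, "ter_ter": 3,
             "bi_bi": 2, "gr_bi_ter": 2}[mechanism]
    for _ in range(50):
        p = random_positive_params(rng, mechanism)
        subs = np.exp(rng.uniform(-2, 1, size=n_sub))
        n_prod = len(info.roles) - n_sub
        prods = np.exp(rng.uniform(-2, 1, size=n_prod))
        target = np.prod(subs) * p.keq
        if mechanism == "gr_bi_ter":
            # products are NADP and GSH (squared)
            gsh = prods[1]
            prods[0] = target / gsh ** 2
            args = [subs[0], subs[1], prods[0], gsh]
        else:
            prods[0] = target / np.prod(prods[1:]) if n_prod > 1 else target
            args = list(subs) + list(prods)
        v = info.fn(p, *args)
        scale = max(p.vmaxf, 1.0)
        assert abs(v) < 1e-9 * scale


@pytest.mark.parametrize("mechanism", sorted(set(MECHANISMS) -
                                             {"constant_flux"}))
def test_rate_bounded_by_limiting_rates(mechanism):
    """Forward rate never exceeds Vmaxf; explicit reverse limiting rates
    bound the backward direction.  (Single-Vmax reversible forms have an
    implied Haldane reverse limit instead, which is not asserted.)"""
    rng = np.random.default_rng(11)
    info = MECHANISMS[mechanism]
    two_v = mechanism in ("uni_uni_2V", "bi_bi_2V", "gdh_mwc")
    for _ in range(300):
        p = random_positive_params(rng, mechanism)
        c = np.exp(rng.uniform(-6, 4, size=len(info.roles)))
        v = info.fn(p, *c)
        if v >= 0:
            assert v <= p.vmaxf * (1 + 1e-9)
        elif two_v:
            assert -v <= p.vmaxr * (1 + 1e-9)


MONOTONE_CASES = [
    # (mechanism, substrate indices, product indices)
    ("ter_bi", (0, 1, 2), (3, 4)),
    ("random_bi_bi", (0, 1), (2, 3)),
    ("uni_uni", (0,), (1,)),
    ("ter_ter", (0, 1, 2), (3, 4, 5)),
    ("bi_bi", (0, 1), (2, 3)),
    ("uni_uni_2V", (0,), (1,)),
    ("bi_bi_2V", (0, 1), (2, 3)),
    ("gr_bi_ter", (0, 1), (2, 3)),
]


@pytest.mark.parametrize("mechanism,subs,prods", MONOTONE_CASES)
def test_monotone_in_substrates_and_products(mechanism, subs, prods):
    rng = np.random.default_rng(13)
    info = MECHANISMS[mechanism]
    for _ in range(40):
        p = random_positive_params(rng, mechanism)
        base = np.exp(rng.uniform(-2, 1, size=len(info.roles)))
        for i in subs + prods:
            grid = np.linspace(base[i] * 0.2, base[i] * 5.0, 12)
            vals = []
            for g in grid:
                c = base.copy()
                c[i] = g
                vals.append(info.fn(p, *c))
            diffs = np.diff(vals)
            if i in subs:
                assert np.all(diffs >= -1e-9 * max(1, abs(vals[0])))
            else:
                assert np.all(diffs <= 1e-9 * max(1, abs(vals[0])))


def test_missing_constant_raises_named_error():
    with pytest.raises(ConfigurationError, match="Kb"):
        KineticParameterSet("x", "bi_bi", vmaxf=1.0,
                            km={"Ka": 1, "Kp": 1, "Kq": 1}, keq=1.0)


def test_evaluate_dispatch():
    p = KineticParameterSet("x", "uni_uni", vmaxf=2.0,
                            km={"Ka": 1.0, "Kp": 1.0}, keq=10.0)
    v = evaluate(p, {"A": 1.0, "P": 0.0})
    assert v == pytest.approx(rate_uni_uni(p, 1.0, 0.0))
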