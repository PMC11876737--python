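"""Decay-chain physics: closed forms against independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pb212pk.decay import (
    Inventory,
    Nuclide,
    NuclideChain,
    bateman_evolve,
    chain_activity_ratio,
    convert_activity,
    decay_factor,
    pb212_chain,
)

from .oracles import ode_chain_activities


class TestDecayFactor:
    @pytest.mark.parametrize(
        "elapsed, half_life, expected",
        [
            (0.0, 10.64, 1.0),
            (10.64, 10.64, 0.5),
            (6.0, 10.64, 2 ** (-6 / 10.64)),  # = 0.67645...
        ],
    )
    def test_values(self, elapsed, half_life, expected):
        assert decay_factor(elapsed, half_life) == pytest.approx(expected, rel=1e-12)

    def test_six_hour_factor_matches_printed_calibrator_reading(self):
        # 414.4 MBq of freshly eluted parent decayed 6 h lands within 2%
        # of the 277.87 MBq bench measurement
        assert 414.4 * decay_factor(6.0, 10.64) == pytest.approx(277.87, rel=0.02)
        assert round(414.4 * decay_factor(6.0, 10.64), 1) == 280.3

    @pytest.mark.parametrize("elapsed, half_life", [(-1.0, 10.0), (1.0, 0.0), (1.0, -2.0)])
    def test_rejects_bad_inputs(self, elapsed, half_life):
        with pytest.raises(ValueError):
            decay_factor(elapsed, half_life)

    @given(
        a=st.floats(0, 100, allow_nan=False),
        b=st.floats(0, 100, allow_nan=False),
    )
    def test_multiplicative(self, a, b):
        f = lambda t: decay_factor(t, 10.64)  # noqa: E731
        assert abs(f(a + b) - f(a) * f(b)) < 1e-12


class TestConvertActivity:
    @pytest.mark.parametrize(
        "value, frm, to, expected",
        [
            (444.0, "MBq", "mCi", 12.0),
            (0.37, "MBq", "uCi", 10.0),
            (1.0, "Ci", "GBq", 37.0),
            (1.0, "uCi", "kBq", 37.0),
        ],
    )
    def test_exact_conversions(self, value, frm, to, expected):
        assert convert_activity(value, frm, to) == pytest.approx(expected, rel=1e-12)

    def test_round_trip(self):
        assert convert_activity(
            convert_activity(3.14, "MBq", "uCi"), "uCi", "MBq"
        ) == pytest.approx(3.14, rel=1e-12)

    def test_unknown_unit(self):
        with pytest.raises(ValueError, match="unknown activity unit"):
            convert_activity(1.0, "MBq", "furlong")


class TestBateman:
    def test_zero_elapsed_is_identity(self, chain):
        inv = Inventory({"pb212": 1e15})
        out = bateman_evolve(chain, inv, 0.0)
        assert out.atoms["pb212"] == pytest.approx(1e15, rel=1e-12)
        assert sum(v for k, v in out.atoms.items() if k != "pb212") < 1e-6 * 1e15

    @pytest.mark.parametrize("elapsed", [0.5, 3.0, 21.28, 100.0])
    def test_atom_conservation(self, chain, elapsed):
        inv = Inventory({"pb212": 1e15})
        out = bateman_evolve(chain, inv, elapsed)
        assert out.total_atoms() == pytest.approx(1e15, rel=1e-9)

    def test_parent_activity_is_pure_exponential(self, chain):
        inv = Inventory.from_activity(chain, "pb212", 1e6)
        for t in (0.1, 5.0, 42.0):
            out = bateman_evolve(chain, inv, t)
            assert out.activity_bq(chain, "pb212") == pytest.approx(
                1e6 * decay_factor(t, 10.64), rel=1e-12
            )

    def test_closed_form_matches_ode_oracle(self, chain):
        """Relative error < 1e-6 against stiff Radau integration at 100 times."""
        rng = np.random.default_rng(7)
        times = np.sort(rng.uniform(0.01, 120.0, size=100))
        inv0 = Inventory.from_activity(chain, "pb212", 1e6)
        oracle = ode_chain_activities(chain, {"pb212": 1e6}, times)
        for i, t in enumerate(times):
            out = bateman_evolve(chain, inv0, t)
            for name in ("pb212", "bi212", "po212", "tl208"):
                ref = oracle[name][i]
                if ref > 1e-9 * 1e6:
                    assert out.activity_bq(chain, name) == pytest.approx(
                        ref, rel=1e-6
                    ), (name, t)

    def test_transient_equilibrium_bi_over_pb(self, chain):
        """A(²¹²Bi)/A(²¹²Pb) → λ_Bi/(λ_Bi−λ_Pb) ≈ 1.105."""
        lam_pb = chain["pb212"].lam
        lam_bi = chain["bi212"].lam
        expected = lam_bi / (lam_bi - lam_pb)
        assert expected == pytest.approx(1.105, abs=5e-4)
        inv = bateman_evolve(chain, Inventory({"pb212": 1e15}), 30.0)
        ratio = inv.activity_bq(chain, "bi212") / inv.activity_bq(chain, "pb212")
        assert ratio == pytest.approx(expected, rel=1e-4)

    def test_unknown_nuclide_rejected(self, chain):
        with pytest.raises(KeyError):
            bateman_evolve(chain, Inventory({"ra224": 1.0}), 1.0)

    def test_degenerate_rates_use_limiting_form(self):
        """Two equal half-lives: closed form falls back without blowing up."""
        chain = NuclideChain(
            (
                Nuclide("a", 2.0, (("b", 1.0),)),
                Nuclide("b", 2.0, (("c", 1.0),)),
                Nuclide("c", None),
            ),
            root="a",
        )
        lam = math.log(2) / 2.0
        out = bateman_evolve(chain, Inventory({"a": 1e12}), 3.0)
        # exact confluent solution: N_b = N0 λ t e^{-λt}
        assert out.atoms["b"] == pytest.approx(
            1e12 * lam * 3.0 * math.exp(-lam * 3.0), rel=1e-9
        )
        assert out.total_atoms() == pytest.approx(1e12, rel=1e-9)


class TestChainActivityRatio:
    def test_fresh_parent_is_one(self, chain):
        inv = Inventory({"pb212": 1e15})
        assert chain_activity_ratio(chain, inv) == pytest.approx(1.0)

    def test_equilibrium_value_matches_ode_oracle(self, chain):
        """Evolve ≥10 parent half-lives; compare with the ODE integration."""
        t = 110.0  # > 10 × 10.64 h
        inv = bateman_evolve(chain, Inventory({"pb212": 1e18}), t)
        got = chain_activity_ratio(chain, inv)
        oracle = ode_chain_activities(chain, {"pb212": 1e6}, [t])
        expected = sum(v[0] for v in oracle.values()) / oracle["pb212"][0]
        assert got == pytest.approx(expected, rel=1e-6)
        # gross-current instruments see ~3.2x the parent-only activity
        assert 3.0 < got < 3.4

    def test_stable_daughter_chain_stays_at_one(self):
        chain = NuclideChain(
            (Nuclide("a", 5.0, (("b", 1.0),)), Nuclide("b", None)), root="a"
        )
        for t in (0.0, 1.0, 10.0):
            inv = bateman_evolve(chain, Inventory({"a": 1e12}), t)
            assert chain_activity_ratio(chain, inv) == pytest.approx(1.0, rel=1e-12)

    def test_zero_root_activity_rejected(self, chain):
        with pytest.raises(ValueError):
            chain_activity_ratio(chain, Inventory({"bi212": 1e12}))


class TestChainValidation:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            NuclideChain(
                (
                    Nuclide("a", 1.0, (("b", 1.0),)),
                    Nuclide("b", 1.0, (("a", 1.0),)),
                ),
                root="a",
            )

    def test_branch_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="branching"):
            Nuclide("a", 1.0, (("b", 0.5), ("c", 0.3)))

    def test_missing_branch_target_rejected(self):
        with pytest.raises(ValueError, match="unknown nuclide"):
            NuclideChain((Nuclide("a", 1.0, (("zz", 1.0),)),), root="a")
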