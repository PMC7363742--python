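import math
from fractions import Fraction

import pytest

from pedident import (
    INFINITE,
    HalfCousinSpec,
    InadmissibleError,
    build_chain,
    build_dhc,
    build_half_cousin,
    ibd_to_dhc,
    ibd_triple,
    kinship,
    kinship_chain,
    kinship_to_half_cousin,
    stationary_inbreeding,
    triangle_regions,
    triangle_vertex,
)


class TestKinshipToHalfCousin:
    @pytest.mark.parametrize(
        "phi, m, f",
        [
            (Fraction(25, 64), 1, Fraction(9, 16)),  # 0.390625 -> (1, 0.5625)
            (1, 0, 1),
            (Fraction(1, 4), 1, 0),  # dyadic: natural output
            (Fraction(1, 3), 1, Fraction(1, 3)),
            (Fraction(1, 7), 2, Fraction(1, 7)),
        ],
    )
    def test_inversion(self, phi, m, f):
        spec = kinship_to_half_cousin(phi)
        assert (spec.m, spec.founder_f) == (m, f)
        if phi:
            assert spec.kinship() == phi  # closed-form round trip is exact

    def test_zero_maps_to_infinite_separation(self):
        spec = kinship_to_half_cousin(0)
        assert spec.m == INFINITE and spec.founder_f == 0

    def test_prefer_inbred_alternative_for_dyadic(self):
        spec = kinship_to_half_cousin(Fraction(1, 4), prefer_inbred=True)
        assert (spec.m, spec.founder_f) == (2, 1)
        assert spec.kinship() == Fraction(1, 4)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            kinship_to_half_cousin(Fraction(3, 2))


class TestBuildHalfCousin:
    def test_parent_child_shape(self):
        ped, (a, b) = build_half_cousin(HalfCousinSpec(1, 0))
        assert ped.parents(a) is not None and ped.parents(b) is None
        assert kinship(ped, a, b) == Fraction(1, 4)

    def test_degenerate_self_pair(self):
        ped, (a, b) = build_half_cousin(HalfCousinSpec(0, Fraction(1, 2)))
        assert a == b and len(ped) == 1
        assert kinship(ped, a, b) == Fraction(3, 4)

    def test_infinite_separation_unrelated(self):
        ped, (a, b) = build_half_cousin(HalfCousinSpec(INFINITE, 0))
        assert kinship(ped, a, b) == 0

    @pytest.mark.parametrize("m", range(7))
    @pytest.mark.parametrize("f", [0, Fraction(1, 4), 1])
    def test_closed_form_kinship(self, m, f):
        ped, (a, b) = build_half_cousin(HalfCousinSpec(m, f))
        assert ped.validate() == []
        assert kinship(ped, a, b) == Fraction(1, 2 ** (m + 1)) * (1 + f)


class TestKinshipChain:
    def test_example_increments(self):
        spec = kinship_chain(Fraction(25, 64))
        assert spec.increments == (2, 1, 3) and spec.exact

    def test_single_bit(self):
        spec = kinship_chain(Fraction(1, 2))
        assert spec.increments == (1,) and spec.exact

    def test_non_dyadic_truncation(self):
        spec = kinship_chain(Fraction(1, 3), max_terms=4)
        assert spec.increments == (2, 2, 2, 2)
        assert not spec.exact
        assert spec.residual == Fraction(1, 3) - sum(
            Fraction(1, 4) ** k for k in range(1, 5)
        )
        assert 0 < spec.residual < Fraction(1, 2**8)

    def test_rejects_zero(self):
        with pytest.raises(ValueError, match="infinitely distant"):
            kinship_chain(0)


class TestBuildChain:
    def test_selfing_layer(self):
        spec = kinship_chain(Fraction(1, 2))
        ped, (a, b) = build_chain(spec)
        assert kinship(ped, a, b) == Fraction(1, 2)

    def test_three_layer_example(self):
        ped, (a, b) = build_chain(kinship_chain(Fraction(25, 64)))
        assert ped.selfing_allowed  # middle layer is a selfing step
        assert kinship(ped, a, b) == Fraction(25, 64)

    @pytest.mark.parametrize(
        "phi",
        [Fraction(1, 2), Fraction(3, 8), Fraction(5, 16), Fraction(21, 64),
         Fraction(1, 16), Fraction(15, 16), Fraction(29, 128)],
    )
    def test_round_trip_dyadic(self, phi):
        spec = kinship_chain(phi)
        assert spec.exact
        ped, (a, b) = build_chain(spec)
        assert ped.validate() == []
        assert kinship(ped, a, b) == phi

    def test_truncated_chain_error_bound(self):
        spec = kinship_chain(Fraction(1, 3), max_terms=6)
        ped, (a, b) = build_chain(spec)
        achieved = kinship(ped, a, b)
        assert abs(achieved - Fraction(1, 3)) <= Fraction(1, 2 ** sum(spec.increments))


class TestIbdToDhc:
    def test_example_quadruple_half_first_cousins_point(self):
        sol = ibd_to_dhc((Fraction(17, 32), Fraction(14, 32), Fraction(1, 32)))
        assert (sol.m, sol.n) == (3, 1)
        assert sol.f1 == pytest.approx(3 - 2 * math.sqrt(2), abs=1e-12)
        assert sol.f2 == pytest.approx(math.sqrt(2) / 2, abs=1e-12)
        assert sol.U == Fraction(1, 2) and sol.D == Fraction(1, 8)

    def test_unrelated_vertex(self):
        sol = ibd_to_dhc((1, 0, 0))
        assert sol.m == INFINITE and sol.n == INFINITE

    def test_monozygotic_vertex(self):
        sol = ibd_to_dhc((0, 0, 1))
        assert (sol.m, sol.n, sol.f1, sol.f2) == (0, 0, 1, 1)

    def test_inadmissible_rejected(self):
        with pytest.raises(InadmissibleError):
            ibd_to_dhc((Fraction(1, 2), 0, Fraction(1, 2)))

    def test_kappa_factorization_round_trip(self):
        target = (Fraction(17, 32), Fraction(14, 32), Fraction(1, 32))
        k = ibd_to_dhc(target).kappa()
        assert k.kappa0 == pytest.approx(float(target[0]), abs=1e-12)
        assert k.kappa2 == pytest.approx(float(target[2]), abs=1e-12)


class TestBuildDhc:
    def test_built_pedigree_reproduces_target_triple(self):
        sol = ibd_to_dhc((Fraction(17, 32), Fraction(14, 32), Fraction(1, 32)))
        ped, (a, b) = build_dhc(sol)
        assert ped.validate() == []
        k = ibd_triple(ped, a, b)
        assert k.kappa0 == pytest.approx(17 / 32, abs=1e-12)
        assert k.kappa1 == pytest.approx(14 / 32, abs=1e-12)
        assert k.kappa2 == pytest.approx(1 / 32, abs=1e-12)

    def test_edge_interpolation(self):
        # f1 = 1 pins one side; f2 = lambda moves along the V_{1,0} edge
        lam = Fraction(1, 3)
        from pedident import DHCSolution

        ped, (a, b) = build_dhc(
            DHCSolution(
                m=1, n=0, f1=Fraction(1), f2=lam, U=None, D=None,
                phi1=Fraction(1, 2), phi2=Fraction(1, 2) * (1 + lam),
            )
        )
        k = ibd_triple(ped, a, b)
        v_a, v_b = triangle_vertex(1, 0), triangle_vertex(1, 1)
        assert k.kappa0 == lam * v_a[0] + (1 - lam) * v_b[0]
        assert k.kappa2 == lam * v_a[1] + (1 - lam) * v_b[1]

    @pytest.mark.parametrize(
        "target",
        [
            (Fraction(1, 4), Fraction(1, 2), Fraction(1, 4)),
            (Fraction(9, 16), Fraction(6, 16), Fraction(1, 16)),
            (Fraction(2, 5), Fraction(1, 2), Fraction(1, 10)),
            (Fraction(7, 10), Fraction(28, 100), Fraction(1, 50)),
            (Fraction(3, 8), Fraction(5, 8), Fraction(0)),
            (1, 0, 0),
        ],
    )
    def test_round_trip_admissible_grid(self, target):
        ped, (a, b) = build_dhc(ibd_to_dhc(target))
        k = ibd_triple(ped, a, b)
        for got, want in zip(k, target):
            assert float(got) == pytest.approx(float(want), abs=1e-10)


class TestTriangle:
    @pytest.mark.parametrize(
        "i, j, expected",
        [
            (0, 0, (0, 1)),
            (1, 1, (Fraction(1, 4), Fraction(1, 4))),
            (INFINITE, 2, (Fraction(3, 4), 0)),
            (INFINITE, INFINITE, (1, 0)),
        ],
    )
    def test_vertices(self, i, j, expected):
        assert triangle_vertex(i, j) == expected

    def test_point_s_in_three_regions(self):
        regions = triangle_regions((Fraction(1, 4), Fraction(1, 4)))
        assert sorted((r.m, r.n) for r in regions) == [(0, 0), (1, 0), (1, 1)]

    def test_point_q_single_region(self):
        regions = triangle_regions((Fraction(17, 32), Fraction(1, 32)))
        assert [(r.m, r.n) for r in regions] == [(3, 1)]

    def test_unrelated_vertex_region(self):
        regions = triangle_regions((1, 0))
        assert [(r.m, r.n) for r in regions] == [(INFINITE, INFINITE)]

    def test_bottom_edge_segments(self):
        regions = triangle_regions((Fraction(3, 8), 0))
        assert [(r.m, r.n) for r in regions] == [(INFINITE, 0)]

    def test_inadmissible_point_rejected(self):
        with pytest.raises(InadmissibleError):
            triangle_regions((Fraction(1, 2), Fraction(1, 2)))

    def test_barycentric_weights_reproduce_point(self):
        for target in [
            (Fraction(1, 4), Fraction(1, 4)),
            (Fraction(17, 32), Fraction(1, 32)),
            (Fraction(2, 5), Fraction(1, 10)),
        ]:
            for r in triangle_regions(target):
                x = sum(w * v[0] for w, v in zip(r.weights, r.vertices))
                y = sum(w * v[1] for w, v in zip(r.weights, r.vertices))
                assert float(x) == pytest.approx(float(target[0]), abs=1e-12)
                assert float(y) == pytest.approx(float(target[1]), abs=1e-12)
                assert all(w >= -1e-12 for w in r.weights)
                assert float(sum(r.weights)) == pytest.approx(1, abs=1e-12)

    def test_interior_regions_match_solver(self, rng):
        """Interior points return exactly one cell, the solver's (m, n)."""
        found = 0
        while found < 10:
            k0 = Fraction(int(rng.integers(1, 60)), 64)
            k2 = Fraction(int(rng.integers(1, 60)), 64)
            k1 = 1 - k0 - k2
            if k1 < 0 or k1 * k1 < 4 * k0 * k2:
                continue
            regions = triangle_regions((k0, k2))
            assert regions
            sol = ibd_to_dhc((k0, k1, k2))
            if len(regions) == 1:
                assert (regions[0].m, regions[0].n) == (sol.m, sol.n)
            else:
                assert (sol.m, sol.n) in [(r.m, r.n) for r in regions]
            found += 1

    def test_bilinear_convex_combination_identity(self):
        """kappa of DHC_{m,n}^{f1,f2} equals the bilinear vertex mix on a grid."""
        for m, n in [(0, 0), (1, 0), (2, 1), (3, 1)]:
            for f1 in (0, Fraction(1, 4), Fraction(3, 4), 1):
                for f2 in (0, Fraction(1, 2), 1):
                    phi1 = Fraction(1, 2 ** (m + 1)) * (1 + f1)
                    phi2 = Fraction(1, 2 ** (n + 1)) * (1 + f2)
                    k0 = (1 - phi1) * (1 - phi2)
                    k2 = phi1 * phi2
                    mix0 = (
                        f1 * f2 * triangle_vertex(m, n)[0]
                        + f1 * (1 - f2) * triangle_vertex(m, n + 1)[0]
                        + (1 - f1) * f2 * triangle_vertex(m + 1, n)[0]
                        + (1 - f1) * (1 - f2) * triangle_vertex(m + 1, n + 1)[0]
                    )
                    mix2 = (
                        f1 * f2 * triangle_vertex(m, n)[1]
                        + f1 * (1 - f2) * triangle_vertex(m, n + 1)[1]
                        + (1 - f1) * f2 * triangle_vertex(m + 1, n)[1]
                        + (1 - f1) * (1 - f2) * triangle_vertex(m + 1, n + 1)[1]
                    )
                    assert (k0, k2) == (mix0, mix2)


class TestStationaryInbreeding:
    def test_half_sib_scheme(self):
        # half sibs have separation 2; repeated half-sib mating settles at 1/7
        assert stationary_inbreeding(2) == Fraction(1, 7)

    def test_closed_form_small_m(self):
        assert stationary_inbreeding(0) == 1
        assert stationary_inbreeding(1) == Fraction(1, 3)

    @pytest.mark.parametrize("m", range(5))
    def test_fixed_point_property(self, m):
        f_star = stationary_inbreeding(m)
        ped, (a, b) = build_half_cousin(HalfCousinSpec(m, f_star))
        assert kinship(ped, a, b) == f_star
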