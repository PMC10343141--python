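import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import composkern as ck
from composkern.errors import InvalidInputError, ZeroHandlingError
from composkern.kernels import (
    FAMILIES,
    KernelSpec,
    default_kernel_grid,
    gram_matrix,
    induced_distance,
    is_psd,
    kernel_eval,
    psd_clip,
)
from composkern.simplex import barycenter, clr_shift

from conftest import random_simplex

ALL_SPECS = [
    KernelSpec("linear"),
    KernelSpec("rbf", g=2.0),
    KernelSpec("aitchison", c=1e-3),
    KernelSpec("aitchison-rbf", c=1e-3, g=0.5),
    KernelSpec("prob-js"),
    KernelSpec("prob-hellinger"),
    KernelSpec("prob-tv"),
    KernelSpec("prob-chisq"),
    KernelSpec("heat-diffusion", t=0.5),
]

NON_HEAT_SPECS = [s for s in ALL_SPECS if s.family != "heat-diffusion"]


class TestKernelSpec:
    def test_missing_params_rejected(self):
        with pytest.raises(InvalidInputError):
            KernelSpec("rbf")
        with pytest.raises(InvalidInputError):
            KernelSpec("aitchison")
        with pytest.raises(InvalidInputError):
            KernelSpec("heat-diffusion")

    def test_extraneous_params_rejected(self):
        with pytest.raises(InvalidInputError):
            KernelSpec("linear", g=1.0)
        with pytest.raises(InvalidInputError):
            KernelSpec("prob-js", t=1.0)

    def test_unknown_family(self):
        with pytest.raises(InvalidInputError):
            KernelSpec("polynomial")

    def test_roundtrip_dict(self):
        spec = KernelSpec("aitchison-rbf", c=0.01, g=3.0)
        assert KernelSpec.from_dict(spec.to_dict()) == spec


class TestKernelEval:
    def test_linear_disjoint_support(self):
        assert kernel_eval(KernelSpec("linear"), [1, 0], [0, 1]) == 0.0

    def test_unit_self_similarity(self):
        x = np.array([0.3, 0.3, 0.4])
        assert kernel_eval(KernelSpec("rbf", g=7.0), x, x) == pytest.approx(1.0)
        assert kernel_eval(KernelSpec("heat-diffusion", t=0.1), x, x) == pytest.approx(1.0)

    def test_aitchison_barycenter_zero(self):
        u = barycenter(4)
        assert kernel_eval(KernelSpec("aitchison", c=0.0), u, u) == pytest.approx(0.0)

    def test_hellinger_hand_value(self):
        # p=2, anchor (1/2, 1/2): delta(x,y)=2, delta to anchor = 2 - sqrt(2)
        k = kernel_eval(KernelSpec("prob-hellinger"), [1, 0], [0, 1])
        assert k == pytest.approx(1 - np.sqrt(2), abs=1e-12)

    def test_mismatched_p(self):
        with pytest.raises(InvalidInputError):
            kernel_eval(KernelSpec("linear"), [0.5, 0.5], [0.2, 0.3, 0.5])

    def test_aitchison_zero_handling(self):
        with pytest.raises(ZeroHandlingError):
            kernel_eval(KernelSpec("aitchison", c=0.0), [1, 0], [0.5, 0.5])

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.family)
    def test_symmetry_and_cauchy_schwarz(self, spec, rng):
        X = random_simplex(rng, 12, 5, sparsity=0.3)
        if spec.family in ("aitchison", "aitchison-rbf"):
            X = random_simplex(rng, 12, 5)  # interior for c-free comparison
        for i in range(0, 12, 3):
            for j in range(1, 12, 4):
                kxy = kernel_eval(spec, X[i], X[j])
                kyx = kernel_eval(spec, X[j], X[i])
                assert kxy == pytest.approx(kyx, abs=1e-12)
                kxx = kernel_eval(spec, X[i], X[i])
                kyy = kernel_eval(spec, X[j], X[j])
                assert kxy ** 2 <= kxx * kyy + 1e-10


class TestGram:
    def test_single_point(self):
        T = ck.CompositionTable(np.array([[0.2, 0.8]]))
        G = gram_matrix(KernelSpec("linear"), T)
        assert G.values.shape == (1, 1)
        assert G.values[0, 0] == pytest.approx(0.2 ** 2 + 0.8 ** 2)

    @pytest.mark.parametrize("spec", NON_HEAT_SPECS, ids=lambda s: s.family)
    def test_psd_50_random_points(self, spec, rng):
        X = random_simplex(rng, 50, 6, sparsity=0.0 if "aitchison" in spec.family else 0.4)
        assert is_psd(gram_matrix(spec, X).values)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.family)
    def test_cross_gram_transpose(self, spec, rng):
        A = ck.CompositionTable(random_simplex(rng, 7, 4))
        B = ck.CompositionTable(random_simplex(rng, 5, 4))
        Kab = gram_matrix(spec, A, B).values
        Kba = gram_matrix(spec, B, A).values
        np.testing.assert_allclose(Kab, Kba.T, atol=1e-12)

    @pytest.mark.parametrize("p", [3, 10, 50])
    @pytest.mark.parametrize("spec", NON_HEAT_SPECS, ids=lambda s: s.family)
    def test_psd_suite_sparse(self, spec, p, rng):
        """PSD on 200 random sparse simplex points per non-heat family."""
        sparse = 0.0 if "aitchison" in spec.family else 0.5
        X = random_simplex(rng, 200, p, sparsity=sparse)
        assert is_psd(gram_matrix(spec, X).values)

    def test_psd_clip_repairs(self, rng):
        X = random_simplex(rng, 60, 8, sparsity=0.5)
        K = gram_matrix(KernelSpec("heat-diffusion", t=2.0), X).values
        R = psd_clip(K)
        assert is_psd(R)
        # repair only moves the matrix by the size of the negative spectrum
        w = np.linalg.eigvalsh(K)
        assert np.linalg.norm(R - K) <= abs(min(w.min(), 0)) * np.sqrt(len(w)) + 1e-10


class TestInducedDistance:
    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.family)
    def test_zero_at_equal_points(self, spec):
        x = np.array([0.25, 0.3, 0.45])
        assert induced_distance(spec, x, x) == pytest.approx(0.0, abs=1e-7)

    def test_linear_is_euclidean(self, rng):
        X = random_simplex(rng, 6, 5)
        for i in range(5):
            d = induced_distance(KernelSpec("linear"), X[i], X[i + 1])
            assert d == pytest.approx(np.linalg.norm(X[i] - X[i + 1]))

    def test_aitchison_is_clr_euclidean(self, rng):
        X = random_simplex(rng, 6, 5)
        c = 1e-4
        for i in range(5):
            d = induced_distance(KernelSpec("aitchison", c=c), X[i], X[i + 1])
            expected = np.linalg.norm(clr_shift(X[i], c) - clr_shift(X[i + 1], c))
            assert d == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.family)
    def test_semi_metric_axioms(self, spec, rng):
        X = random_simplex(rng, 8, 4, sparsity=0.0 if "aitchison" in spec.family else 0.3)
        for i in range(0, 8, 2):
            for j in range(1, 8, 2):
                d = induced_distance(spec, X[i], X[j])
                assert d >= 0
                assert d == pytest.approx(induced_distance(spec, X[j], X[i]), abs=1e-10)

    @pytest.mark.parametrize("spec", [
        KernelSpec("linear"),
        KernelSpec("aitchison", c=1e-3),
        KernelSpec("prob-hellinger"),
    ], ids=lambda s: s.family)
    def test_triangle_inequality(self, spec, rng):
        X = random_simplex(rng, 9, 5)
        for a in range(0, 9, 3):
            for b in range(1, 9, 3):
                for c in range(2, 9, 3):
                    dab = induced_distance(spec, X[a], X[b])
                    dbc = induced_distance(spec, X[b], X[c])
                    dac = induced_distance(spec, X[a], X[c])
                    assert dac <= dab + dbc + 1e-10


class TestDefaultGrid:
    def test_exactly_55(self, small_table):
        assert len(default_kernel_grid(small_table)) == 55

    def test_all_families_present(self, small_table):
        grid = default_kernel_grid(small_table)
        assert {s.family for s in grid} == set(FAMILIES)

    def test_deterministic(self, small_table):
        g1 = default_kernel_grid(small_table)
        g2 = default_kernel_grid(small_table)
        assert g1 == g2

    def test_specs_valid(self, small_table):
        for spec in default_kernel_grid(small_table):
            KernelSpec(**{k: v for k, v in spec.to_dict().items()})
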