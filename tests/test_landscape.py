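"""PCA, Maclaurin reweighting, FES construction and selection statistics."""

import numpy as np
import pytest
from scipy import integrate

from surfplast import (
    BoostSeries,
    StructureEnsemble,
    binding_competence,
    fit_pca,
    maclaurin_weights,
    make_reference_structure,
    population_shift,
    reweighted_fes,
    sample_toy_gamd,
)
from surfplast.ensemble import KB_KCAL
from surfplast.errors import CorrespondenceError, GeometryError, InsufficientFramesError
from surfplast.landscape import _count_local_minima
from surfplast.synthetic import double_well_spec

from conftest import gaussian_ensemble, static_ensemble


def displaced_ensemble(n_atoms, n_frames, seed, scale=1.0):
    """Frames displaced along one fixed random unit direction, c ~ N(0, scale^2)."""
    ref = make_reference_structure(n_atoms, "helix")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal((n_atoms, 3))
    direction /= np.linalg.norm(direction)
    c = scale * rng.standard_normal(n_frames)
    coords = ref.coords[0][None] + c[:, None, None] * direction[None]
    return StructureEnsemble(ref.atoms, coords), direction, c


class TestPCA:
    def test_single_mode_recovery(self):
        ens, direction, c = displaced_ensemble(10, 2000, seed=1)
        model = fit_pca(ens, 3)
        cos = abs(model.components[0] @ direction.ravel())
        assert cos > 0.99
        assert model.eigenvalues[0] == pytest.approx(c.var(), rel=1e-8)

    def test_rank_one_covariance(self):
        ens = static_ensemble(n_atoms=5, n_frames=4)
        coords = ens.coords.copy()
        coords[-1, 2] += np.array([0.5, 0.0, 0.0])
        model = fit_pca(ens.with_coords(coords), 3)
        assert model.eigenvalues[0] > 1e-4
        assert np.all(model.eigenvalues[1:] <= 1e-10)

    def test_matches_brute_force_eigendecomposition(self):
        """SVD route equals explicit covariance + eigh on 20 atoms x 200 frames."""
        ens = gaussian_ensemble(n_atoms=20, n_frames=200, sigma=0.6, seed=9)
        model = fit_pca(ens)
        flat = ens.coords.reshape(200, 60)
        centered = flat - flat.mean(axis=0)
        cov = centered.T @ centered / 200
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        k = model.eigenvalues.size
        np.testing.assert_allclose(model.eigenvalues, evals[:k], atol=1e-8)
        proj_oracle = centered @ evecs[:, :k]
        # align oracle eigenvector signs with the model's convention
        for j in range(k):
            if np.dot(evecs[:, j], model.components[j]) < 0:
                proj_oracle[:, j] *= -1
        np.testing.assert_allclose(model.projections, proj_oracle, atol=1e-8)

    def test_components_orthonormal_and_projections_centered(self):
        ens = gaussian_ensemble(n_atoms=6, n_frames=100, seed=2)
        model = fit_pca(ens, 5)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)
        assert np.abs(model.projections.mean(axis=0)).max() <= 1e-10

    def test_total_variance_conserved(self):
        ens = gaussian_ensemble(n_atoms=7, n_frames=60, seed=3)
        model = fit_pca(ens)  # all available components
        total = model.eigenvalues.sum()
        assert total == pytest.approx(model.total_variance, rel=1e-8)

    def test_insufficient_frames(self):
        with pytest.raises(InsufficientFramesError):
            fit_pca(static_ensemble(n_frames=1), 1)

    def test_project_recovers_training_projections(self):
        ens = gaussian_ensemble(n_atoms=5, n_frames=40, seed=4)
        model = fit_pca(ens, 3)
        np.testing.assert_allclose(
            model.project(ens.coords), model.projections, atol=1e-9
        )


class TestMaclaurinWeights:
    def test_zero_boost_gives_unit_weights(self):
        boost = BoostSeries(np.zeros(7), 300.0)
        for order in (0, 1, 10, None):
            np.testing.assert_array_equal(maclaurin_weights(boost, order), np.ones(7))

    def test_first_order_raw_weight(self):
        beta = 1.0 / (KB_KCAL * 300.0)
        boost = BoostSeries(np.array([0.5 / beta]), 300.0)
        raw = maclaurin_weights(boost, order=1, normalize=False)
        assert raw[0] == pytest.approx(1.5, rel=1e-12)

    def test_order_10_converges_to_e(self):
        beta = 1.0 / (KB_KCAL * 300.0)
        boost = BoostSeries(np.array([1.0 / beta]), 300.0)
        raw = maclaurin_weights(boost, order=10, normalize=False)
        assert abs(raw[0] - np.e) < 1e-7

    def test_monotone_in_order_and_bounded_by_exponential(self):
        rng = np.random.default_rng(6)
        boost = BoostSeries(rng.random(50) * 2.0, 300.0)
        exact = maclaurin_weights(boost, None, normalize=False)
        prev = None
        for order in range(0, 12):
            raw = maclaurin_weights(boost, order, normalize=False)
            assert np.all(raw <= exact + 1e-12)
            if prev is not None:
                assert np.all(raw >= prev)
            prev = raw

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            maclaurin_weights(BoostSeries(np.ones(3), 300.0), -1)


class TestReweightedFES:
    def test_uniform_samples_flat_profile(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.0, 4.0, size=100_000)
        fes = reweighted_fes(x, bins=4, bin_range=[(0.0, 4.0)])
        assert np.nanmax(fes.free_energy) - np.nanmin(fes.free_energy) <= 0.1
        assert fes.probabilities.sum() == pytest.approx(1.0)

    def test_single_occupied_bin(self):
        x = np.full(50, 0.5)
        fes = reweighted_fes(x, bins=5, bin_range=[(0.0, 5.0)])
        assert fes.free_energy[0] == 0.0
        assert np.all(fes.empty[1:])
        assert np.all(np.isnan(fes.free_energy[1:]))

    def test_zero_boost_reweighting_is_identity(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(5000)
        boost = BoostSeries(np.zeros(5000), 300.0)
        w = maclaurin_weights(boost, 10)
        a = reweighted_fes(x, bins=20, bin_range=[(-3, 3)])
        b = reweighted_fes(x, weights=w, bins=20, bin_range=[(-3, 3)])
        np.testing.assert_array_equal(a.probabilities, b.probabilities)
        np.testing.assert_array_equal(
            np.nan_to_num(a.free_energy), np.nan_to_num(b.free_energy)
        )

    def test_gauge_min_is_zero(self):
        rng = np.random.default_rng(9)
        fes = reweighted_fes(rng.standard_normal((2000, 2)), bins=10)
        assert np.nanmin(fes.free_energy) == 0.0

    def test_weight_length_mismatch(self):
        with pytest.raises(ValueError, match="weights"):
            reweighted_fes(np.zeros(10), weights=np.ones(9), bins=4)

    def test_three_dimensional_rejected(self):
        with pytest.raises(ValueError):
            reweighted_fes(np.zeros((10, 3)), bins=4)


def analytic_fes_barrier(spec, edges):
    """Oracle: bin-integrated Boltzmann weights of V by numerical quadrature."""
    beta = 1.0 / (KB_KCAL * spec.temperature)
    p = np.array([
        integrate.quad(lambda x: np.exp(-beta * spec.v(x)), lo, hi)[0]
        for lo, hi in zip(edges[:-1], edges[1:])
    ])
    p /= p.sum()
    f = -np.log(p)
    return f - f.min()


def barrier_height(f, centers):
    """F at the bin nearest x=0, relative to the global minimum (=0)."""
    return f[np.argmin(np.abs(centers))]


class TestGamdReweighting:
    def test_double_well_barrier_recovery(self):
        """Order-10 Maclaurin reweighting recovers the analytic barrier of
        V(x)=(x^2-1)^2 within 0.5 kT; the biased histogram underestimates it."""
        spec = double_well_spec(n_samples=200_000, seed=5)
        xs, boost = sample_toy_gamd(spec)
        edges = np.linspace(-2.0, 2.0, 61)
        centers = 0.5 * (edges[:-1] + edges[1:])

        w = maclaurin_weights(boost, 10)
        fes_rw = reweighted_fes(xs, weights=w, bin_edges=[edges], maclaurin_order=10)
        fes_biased = reweighted_fes(xs, bin_edges=[edges])

        analytic = barrier_height(analytic_fes_barrier(spec, edges), centers)
        measured = barrier_height(fes_rw.free_energy, centers)
        biased = barrier_height(fes_biased.free_energy, centers)
        assert abs(measured - analytic) <= 0.5
        assert biased < measured

    def test_higher_order_reduces_barrier_error(self):
        """|barrier - analytic| shrinks from order 2 to order 10 on average.

        Uses k_boost = 2, which exactly flattens the double well (DeltaV in
        the wells equals the barrier height), so the order-2 truncation
        bias (~0.27 kT) dominates the Metropolis sampling noise.
        """
        edges = np.linspace(-2.0, 2.0, 61)
        centers = 0.5 * (edges[:-1] + edges[1:])
        errs = {2: [], 10: []}
        for seed in range(10):
            spec = double_well_spec(k_boost=2.0, n_samples=100_000, seed=100 + seed)
            xs, boost = sample_toy_gamd(spec)
            analytic = barrier_height(analytic_fes_barrier(spec, edges), centers)
            for order in errs:
                w = maclaurin_weights(boost, order)
                fes = reweighted_fes(xs, weights=w, bin_edges=[edges])
                errs[order].append(
                    abs(barrier_height(fes.free_energy, centers) - analytic)
                )
        assert np.mean(errs[10]) < np.mean(errs[2])


class TestBindingCompetence:
    def test_identical_ensemble_fraction_one(self):
        ens = static_ensemble(n_atoms=8, n_frames=5)
        report = binding_competence(ens, ens.coords[0], cutoff=0.5)
        assert report.competent_fraction == 1.0
        np.testing.assert_allclose(report.rmsd_to_reference, 0.0, atol=1e-10)

    def test_disjoint_geometry_fraction_zero(self):
        ens = static_ensemble(n_atoms=8, n_frames=5)
        report = binding_competence(ens, ens.coords[0] * 5.0, cutoff=1.0)
        assert report.competent_fraction == 0.0

    def test_reference_matched_by_atom_identity(self):
        ens = gaussian_ensemble(n_atoms=6, n_frames=10, sigma=0.1, seed=11)
        ref = make_reference_structure(6, "helix")
        report = binding_competence(ens, ref, cutoff=0.5)
        assert 0.0 <= report.competent_fraction <= 1.0
        assert report.rmsd_to_reference.size == 10

    def test_no_shared_atoms_rejected(self):
        from surfplast.ensemble import AtomRecord

        ens = static_ensemble(n_atoms=4, n_frames=2)
        atoms = [
            AtomRecord(serial=i + 1, name="CA", residue_name="ALA",
                       chain_id="Z", residue_seq=i + 1, element="C")
            for i in range(4)
        ]
        other = StructureEnsemble(atoms, make_reference_structure(4, "helix").coords)
        with pytest.raises(CorrespondenceError):
            binding_competence(ens, other, cutoff=1.0)


class TestPopulationShift:
    def test_identical_fes_no_shift(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(3000)
        edges = np.linspace(-4, 4, 33)
        fes = reweighted_fes(x, bin_edges=[edges])
        shift = population_shift(fes, fes)
        assert shift.range_ratio == [1.0]
        assert shift.minima_difference == 0

    def test_half_range_ratio(self):
        rng = np.random.default_rng(13)
        free = rng.uniform(-1.0, 1.0, 40_000)
        bound = rng.uniform(-0.5, 0.5, 40_000)
        edges = np.linspace(-1.0, 1.0, 21)
        fes_free = reweighted_fes(free, bin_edges=[edges])
        fes_bound = reweighted_fes(bound, bin_edges=[edges])
        shift = population_shift(fes_free, fes_bound)
        assert shift.range_ratio[0] == pytest.approx(0.5, abs=1.0 / 20)

    def test_two_modes_vs_one_minima_difference(self):
        rng = np.random.default_rng(14)
        t = 10_000
        free = np.concatenate([
            rng.normal(-1.5, 0.4, t // 2), rng.normal(1.5, 0.4, t // 2)
        ])
        bound = rng.normal(-1.5, 0.4, t)
        edges = np.linspace(-2.5, 2.5, 26)
        fes_free = reweighted_fes(free, bin_edges=[edges])
        fes_bound = reweighted_fes(bound, bin_edges=[edges])
        shift = population_shift(fes_free, fes_bound)
        assert shift.minima_free == 2
        assert shift.minima_bound == 1
        assert shift.minima_difference == 1

    def test_mismatched_edges_rejected(self):
        x = np.linspace(-1, 1, 100)
        a = reweighted_fes(x, bin_edges=[np.linspace(-1, 1, 11)])
        b = reweighted_fes(x, bin_edges=[np.linspace(-1, 1, 12)])
        with pytest.raises(GeometryError):
            population_shift(a, b)

    def test_plateau_is_not_minimum(self):
        f = np.array([1.0, 0.5, 0.5, 1.0])
        assert _count_local_minima(f) == 0
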