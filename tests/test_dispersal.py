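import numpy as np
import pytest
from scipy import optimize, stats

from stratispread.dispersal import (
    KernelComponent,
    KernelSpec,
    LocalDispersalSpec,
    kernel_spread,
    local_spread,
    neighborhood_offsets,
    sample_distances,
    sample_event_count,
    sample_event_displacement,
)


def half_cauchy_cdf(x, x0, f):
    """P(|C| <= x) for C ~ Cauchy(x0, f); independent closed-form oracle."""
    return (np.arctan((x - x0) / f) + np.arctan((x + x0) / f)) / np.pi


def half_cauchy_median(x0, f):
    return optimize.brentq(lambda q: half_cauchy_cdf(q, x0, f) - 0.5, 0, x0 + 100 * f + 10)


class TestNeighborhoodOffsets:
    def test_full_range1_neighborhood(self):
        offsets = neighborhood_offsets(LocalDispersalSpec(proportion=0.1, range=1))
        assert len(offsets) == 8

    def test_full_range2_neighborhood(self):
        offsets = neighborhood_offsets(LocalDispersalSpec(proportion=0.1, range=2))
        assert len(offsets) == 24

    def test_east_only(self):
        offsets = neighborhood_offsets(
            LocalDispersalSpec(proportion=0.1, shape=("E",), range=1)
        )
        assert offsets.tolist() == [[0, 1]]

    def test_diagonal_requires_both_axis_directions(self):
        offsets = neighborhood_offsets(
            LocalDispersalSpec(proportion=0.1, shape=("N", "E"), range=1)
        )
        assert sorted(map(tuple, offsets.tolist())) == [(-1, 0), (-1, 1), (0, 1)]

    @pytest.mark.parametrize(
        "kwargs", [dict(proportion=1.2), dict(proportion=0.5, shape=()),
                   dict(proportion=0.5, shape=("X",)), dict(proportion=0.5, range=0)]
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LocalDispersalSpec(**kwargs)


class TestLocalSpread:
    def test_zero_proportion_identity(self, rng):
        state = rng.random((5, 5))
        spec = LocalDispersalSpec(proportion=0.0)
        np.testing.assert_array_equal(local_spread(state, spec, rng), state)

    def test_full_emigration_from_interior_cell(self, rng):
        state = np.zeros((5, 5))
        state[2, 2] = 8.0
        spec = LocalDispersalSpec(proportion=1.0, range=1)
        out = local_spread(state, spec, rng)
        assert out[2, 2] == 0.0
        assert out.sum() == pytest.approx(8.0)
        # equal split among the 8 neighbours
        assert out[1, 1] == pytest.approx(1.0)

    def test_deterministic_allocation_conserves_interior_mass(self, rng):
        spec = LocalDispersalSpec(proportion=0.3, range=2)
        for _ in range(1000):
            state = np.zeros((12, 12))
            state[2:-2, 2:-2] = rng.random((8, 8)) * 10
            out = local_spread(state, spec, rng)
            assert out.sum() == pytest.approx(state.sum())

    def test_multinomial_allocation_conserves_integer_mass(self, rng):
        spec = LocalDispersalSpec(proportion=0.5, range=1, allocation="multinomial")
        for _ in range(200):
            state = np.zeros((10, 10))
            state[2:-2, 2:-2] = rng.integers(0, 20, (6, 6)).astype(float)
            out = local_spread(state, spec, rng)
            assert out.sum() == pytest.approx(state.sum())
            assert np.all(out >= 0)

    def test_boundary_migrants_are_absorbed(self, rng):
        state = np.zeros((3, 3))
        state[0, 0] = 8.0  # corner: 5 of 8 neighbours are off-grid
        spec = LocalDispersalSpec(proportion=1.0, range=1)
        out = local_spread(state, spec, rng)
        assert out.sum() == pytest.approx(3.0)

    def test_presence_mode_full_proportion_fills_neighborhood(self, rng):
        state = np.zeros((5, 5), dtype=bool)
        state[2, 2] = True
        spec = LocalDispersalSpec(proportion=1.0, range=1)
        out = local_spread(state, spec, rng, mode="presence")
        assert out.sum() == 9


class TestEventSamplers:
    def test_zero_rate_always_zero(self, rng):
        assert np.all(sample_event_count(0.0, rng, size=1000) == 0)

    def test_poisson_mean_at_case_study_rate(self, rng):
        draws = sample_event_count(3.0, rng, size=100_000)
        se = np.sqrt(3.0 / draws.size)
        assert abs(draws.mean() - 3.0) < 3 * se

    def test_poisson_variance_at_case_study_rate(self, rng):
        lam = 5.0
        draws = sample_event_count(lam, rng, size=100_000)
        # Var(S^2) ~ (mu4 - sigma^4)/n with mu4 = lam + 3 lam^2
        se_var = np.sqrt((lam + 2 * lam**2) / draws.size)
        assert abs(draws.var(ddof=1) - lam) < 3 * se_var

    @pytest.mark.parametrize("x0,f", [(24_752.0, 0.41), (1.0, 0.05)])
    def test_half_cauchy_median_matches_closed_form(self, rng, x0, f):
        spec = KernelSpec(components=(KernelComponent(family="cauchy", x0=x0, scale=f),))
        d = sample_distances(spec, rng, 100_000)
        expected = half_cauchy_median(x0, f)
        # SE of the sample median via the density at the median
        dens = (1 / (np.pi * f)) * (
            1 / (1 + ((expected - x0) / f) ** 2) + 1 / (1 + ((expected + x0) / f) ** 2)
        )
        se = 1.0 / (2 * dens * np.sqrt(d.size))
        assert abs(np.median(d) - expected) < 3 * se

    def test_exponential_component_mean(self, rng):
        spec = KernelSpec(components=(KernelComponent(family="exponential", scale=7.0),))
        d = sample_distances(spec, rng, 100_000)
        assert abs(d.mean() - 7.0) < 3 * 7.0 / np.sqrt(d.size)

    def test_mixture_weights_respected(self, rng):
        spec = KernelSpec(
            components=(
                KernelComponent(weight=0.5, family="cauchy", x0=100.0, scale=0.1),
                KernelComponent(weight=0.5, family="exponential", scale=1.0),
            )
        )
        d = sample_distances(spec, rng, 100_000)
        far = (d > 50).mean()  # essentially all Cauchy draws, no exponential ones
        assert abs(far - 0.5) < 3 * np.sqrt(0.25 / d.size)

    def test_angles_uniform_on_circle(self, rng):
        spec = KernelSpec(components=(KernelComponent(family="cauchy", x0=1, scale=0.05),))
        dx, dy = sample_event_displacement(spec, rng, size=100_000)
        theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
        p = stats.kstest(theta, "uniform", args=(0, 2 * np.pi)).pvalue
        assert p > 0.01

    @pytest.mark.parametrize(
        "kwargs",
        [dict(lambda_events=-1), dict(components=()), dict(propagule_fraction=0.0),
         dict(propagule_fraction=1.5)],
    )
    def test_invalid_kernel_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            KernelSpec(**kwargs)


class TestKernelSpread:
    def test_zero_rate_no_change(self, rng):
        state = np.zeros((5, 5))
        state[2, 2] = 10.0
        spec = KernelSpec(lambda_events=0.0)
        np.testing.assert_array_equal(kernel_spread(state, spec, rng), state)

    def test_empty_state_unchanged(self, rng):
        state = np.zeros((5, 5))
        spec = KernelSpec(lambda_events=5.0)
        np.testing.assert_array_equal(kernel_spread(state, spec, rng), state)

    def test_source_not_debited_and_additions_in_units_of_propagule_size(self, rng):
        state = np.zeros((9, 9))
        state[4, 4] = 10.0
        spec = KernelSpec(
            lambda_events=4.0,
            components=(KernelComponent(family="cauchy", x0=1.0, scale=0.05),),
            propagule_size=2.0,
        )
        out = kernel_spread(state, spec, rng)
        assert out[4, 4] >= 10.0
        added = out.sum() - state.sum()
        assert added == pytest.approx(round(added / 2.0) * 2.0)

    def test_retention_matches_numeric_kernel_integral(self, rng):
        """Fraction of events landing on-grid vs the kernel mass inside the
        grid, computed by angular integration of the distance CDF."""
        x0, f, lam = 8.0, 2.0, 5.0
        half = 10.5  # 21x21 grid, source at centre
        theta = np.linspace(0, 2 * np.pi, 200_001)[:-1]
        border = half / np.maximum(np.abs(np.cos(theta)), np.abs(np.sin(theta)))
        expected = half_cauchy_cdf(border, x0, f).mean()

        state = np.zeros((21, 21))
        state[10, 10] = 10.0
        spec = KernelSpec(
            lambda_events=lam,
            components=(KernelComponent(family="cauchy", x0=x0, scale=f),),
        )
        added = sum(
            kernel_spread(state, spec, rng).sum() - state.sum() for _ in range(400)
        )
        events = 400 * lam  # Poisson-mean events; propagule_size 1
        retained = added / events
        se = np.sqrt(expected * (1 - expected) / events)
        # 4 SE: the Poisson event count adds variance beyond the binomial SE
        assert abs(retained - expected) < 4 * se

    def test_propagule_fraction_scales_with_source_density(self, rng):
        state = np.zeros((15, 15))
        state[7, 7] = 50.0
        spec = KernelSpec(
            lambda_events=10.0,
            components=(KernelComponent(family="cauchy", x0=1.0, scale=0.05),),
            propagule_fraction=0.02,
        )
        out = kernel_spread(state, spec, rng)
        added = out - state
        deposits = added[added > 0]
        assert np.allclose(deposits % 1.0, 0.0)  # multiples of 0.02*50 = 1.0

    def test_presence_mode_marks_destinations(self, rng):
        state = np.zeros((15, 15), dtype=bool)
        state[7, 7] = True
        spec = KernelSpec(lambda_events=20.0,
                          components=(KernelComponent(family="cauchy", x0=1, scale=0.05),))
        out = kernel_spread(state, spec, rng, mode="presence")
        assert out[7, 7]
        assert out.sum() > 1
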