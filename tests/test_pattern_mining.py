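import numpy as np
import pytest

from stdpsync import (
    AfferentPopulationSpec,
    SpikeTrainSet,
    generate_background,
)
from stdpsync.pattern_mining import (
    MiningConfig,
    duration_distribution,
    generate_surrogate,
    mine_and_validate,
    mine_patterns,
    validate_significance,
)

from bruteforce import bf_mine


def _planted(n_repeats=4, jitter=0.0, seed=0, duration=2_000.0, background=None):
    """3-unit template {(0,0),(1,5),(2,12)} planted at regular onsets."""
    rng = np.random.default_rng(seed)
    times, units = [], []
    onsets = 100.0 + 300.0 * np.arange(n_repeats)
    for onset in onsets:
        for u, off in [(0, 0.0), (1, 5.0), (2, 12.0)]:
            times.append(onset + off + (rng.normal(0, jitter) if jitter else 0.0))
            units.append(u)
    if background is not None:
        times.extend(background.events["time"].tolist())
        units.extend(background.events["unit"].tolist())
    n_units = 3 if background is None else max(3, background.n_units)
    return SpikeTrainSet.from_arrays(times, units, n_units, duration), onsets


class TestMinePatterns:
    def test_noise_free_planted_pattern(self):
        """Planted noise-free template is recovered as one pattern."""
        data, _ = _planted(n_repeats=4)
        pats = mine_patterns(data, MiningConfig())
        assert len(pats) == 1
        assert pats[0].n_occurrences == 4
        assert np.allclose(pats[0].durations, 12.0)
        el = pats[0].template.elements
        assert el["unit"].tolist() == [0, 1, 2]
        assert el["rel_time"].tolist() == [0.0, 5.0, 12.0]

    def test_empty_data(self):
        data = SpikeTrainSet.from_arrays([], [], 3, 100.0)
        assert mine_patterns(data, MiningConfig()) == []

    def test_jittered_pattern_recovered(self):
        """With 1 ms jitter every planted occurrence is still recovered.

        Large jitter draws can split occurrences over two templates, but
        pooled over templates every onset is found and durations stay
        within 12 +/- 4 ms.
        """
        data, onsets = _planted(n_repeats=5, jitter=1.0, seed=3)
        pats = mine_patterns(data, MiningConfig(match_tolerance=2.0))
        anchors = np.array([o.anchor for p in pats for o in p.occurrences])
        durations = np.concatenate([p.durations for p in pats])
        for onset in onsets:
            assert np.min(np.abs(anchors - onset)) <= 4.0
        assert np.all(np.abs(durations - 12.0) <= 4.0)

    def test_repeat_indices_increase_with_anchor(self):
        data, _ = _planted(n_repeats=5, jitter=0.5, seed=4)
        (pat,) = mine_patterns(data, MiningConfig())
        anchors = [o.anchor for o in pat.occurrences]
        reps = [o.repeat_index for o in pat.occurrences]
        assert anchors == sorted(anchors)
        assert reps == list(range(1, 6))

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_toys(self, seed):
        """Miner output equals brute-force enumeration on random toy data."""
        rng = np.random.default_rng(seed)
        n_ev = int(rng.integers(10, 50))
        n_units = int(rng.integers(3, 6))
        duration = 500.0
        data = SpikeTrainSet.from_arrays(
            rng.uniform(0, duration, n_ev),
            rng.integers(0, n_units, n_ev),
            n_units,
            duration,
        )
        cfg = MiningConfig(window=50.0, match_tolerance=3.0, min_units=2,
                           min_occurrences=2, dither=10.0)
        mined = mine_patterns(data, cfg)
        oracle = bf_mine(data, cfg.window, cfg.match_tolerance, cfg.min_units,
                         cfg.min_occurrences)
        mined_set = {
            (
                tuple((int(e["unit"]), round(float(e["rel_time"]), 9))
                      for e in p.template.elements),
                tuple((round(o.anchor, 9), round(o.duration, 9))
                      for o in p.occurrences),
            )
            for p in mined
        }
        oracle_set = {
            (
                tuple((u, round(rt, 9)) for u, rt in elements),
                tuple((round(a, 9), round(d, 9)) for a, d in occs),
            )
            for elements, occs in oracle
        }
        assert mined_set == oracle_set


class TestSurrogates:
    def test_per_unit_counts_conserved(self):
        spec = AfferentPopulationSpec(n_units=10, duration=5_000.0, seed=1)
        data = generate_background(spec)
        sur = generate_surrogate(data, MiningConfig(dither=25.0), seed=2)
        assert np.array_equal(sur.counts_per_unit(), data.counts_per_unit())
        assert sur.events["time"].min() >= 0
        assert sur.events["time"].max() < data.duration

    def test_small_dither_limit_approaches_identity(self):
        spec = AfferentPopulationSpec(n_units=5, duration=1_000.0, seed=2)
        data = generate_background(spec)
        cfg = MiningConfig(match_tolerance=1e-12, dither=1e-9)
        sur = generate_surrogate(data, cfg, seed=3)
        assert np.allclose(
            np.sort(sur.events["time"]), np.sort(data.events["time"]), atol=1e-8
        )

    def test_displacement_bounded_by_dither(self):
        spec = AfferentPopulationSpec(n_units=5, duration=10_000.0, seed=3)
        data = generate_background(spec)
        cfg = MiningConfig(dither=25.0)
        sur = generate_surrogate(data, cfg, seed=4)
        # away from boundaries displacement is at most the dither half-width
        for u in range(5):
            a = data.unit_times(u)
            b = sur.unit_times(u)
            interior = (a > 25.0) & (a < data.duration - 25.0)
            if interior.sum() == len(a):  # sortable one-to-one comparison
                assert np.max(np.abs(np.sort(a) - np.sort(b))) <= 50.0

    def test_surrogates_break_planted_coordination(self):
        """Mean validated count on surrogates < count on original."""
        # background sparse enough that many pattern windows stay clean --
        # matching is exact-constellation, so in-window background spikes
        # make an occurrence count as a different candidate
        spec = AfferentPopulationSpec(
            n_units=20, background_rate=0.5, duration=10_000.0, seed=5
        )
        bg = generate_background(spec)
        data, _ = _planted(n_repeats=20, jitter=0.5, seed=5,
                           duration=10_000.0, background=bg)
        cfg = MiningConfig(seed=6)
        n_orig = len(mine_patterns(data, cfg))
        n_sur = [
            len(mine_patterns(generate_surrogate(data, cfg, seed=s), cfg))
            for s in range(10)
        ]
        assert np.mean(n_sur) < n_orig


class _FakePattern:
    """Minimal stand-in with a size class and an occurrence count."""

    def __init__(self, n_elements, n_occurrences):
        from stdpsync.pattern_mining import PatternTemplate

        el = np.zeros(n_elements, dtype=[("unit", "i8"), ("rel_time", "f8")])
        el["unit"] = np.arange(n_elements)
        el["rel_time"] = np.arange(n_elements, dtype=float)
        el["rel_time"] -= el["rel_time"][0]
        self.template = PatternTemplate(el)
        self.n_occurrences = n_occurrences


class TestValidateSignificance:
    def test_zero_surrogates_validates(self):
        pats = [_FakePattern(3, 4)]
        result = validate_significance(pats, [[] for _ in range(20)], alpha=0.01)
        assert result.validated == pats

    def test_tie_with_chance_level_fails(self):
        """Counts equal to the chance quantile are not validated."""
        pats = [_FakePattern(3, 4)]
        # every surrogate also has one size-3 template with 4 occurrences
        sur = [[_FakePattern(3, 4)] for _ in range(20)]
        result = validate_significance(pats, sur, alpha=0.01)
        assert result.validated == []

    def test_quantile_is_max_for_alpha_001_n100(self):
        """With alpha = 0.01 and 100 surrogates the chance level is the max."""
        pats = [_FakePattern(3, 10)]
        counts = list(range(100))  # 0..99 templates per surrogate
        sur = [[_FakePattern(3, 2)] * c for c in counts]
        result = validate_significance(pats, sur, alpha=0.01)
        assert result.chance_levels[3] == 99  # direct order statistic: max
        # original count (1) does not exceed 99 -> nothing validated
        assert result.validated == []

    def test_too_few_surrogates_refused(self):
        with pytest.raises(ValueError):
            validate_significance([_FakePattern(3, 4)], [[]] * 19)


class TestDurationDistribution:
    def test_single_bin(self):
        pats = [_FakePattern(3, 1)]
        pats[0].durations = np.array([12.0, 12.0, 12.0])
        edges, counts, modal = duration_distribution(pats, bin_width=5.0, window=50.0)
        assert counts[2] == 3 and counts.sum() == 3
        assert edges[modal] == 10.0

    def test_empty(self):
        edges, counts, modal = duration_distribution([], bin_width=5.0, window=50.0)
        assert counts.sum() == 0 and modal is None


class TestFalsePositiveControl:
    def test_poisson_rate_bounded(self):
        """On pure Poisson data validated patterns appear in <= 2*alpha of runs."""
        n_fp = 0
        n_runs = 50
        for seed in range(n_runs):
            spec = AfferentPopulationSpec(
                n_units=5, background_rate=20.0, duration=2_000.0,
                pattern_fraction=0.0, seed=seed,
            )
            data = generate_background(spec)
            cfg = MiningConfig(surrogate_n=100, seed=seed)
            result = mine_and_validate(data, cfg)
            n_fp += len(result.validated) > 0
        assert n_fp / n_runs <= 2 * 0.01


class TestRecallOnPlantedTruth:
    @pytest.mark.parametrize("jitter,floor", [(0.0, 1.0), (1.0, 0.9)])
    def test_recall_without_background(self, jitter, floor):
        """Planted occurrences are recovered: 100% noise-free, >=90% jittered.

        Recall is pooled over templates (large jitter draws may split a
        pattern across templates).
        """
        recalled = total = 0
        for seed in range(10):
            data, onsets = _planted(n_repeats=8, jitter=jitter, seed=seed,
                                    duration=3_000.0)
            pats = mine_patterns(data, MiningConfig(match_tolerance=2.0))
            anchors = np.array(
                [o.anchor for p in pats for o in p.occurrences] or [np.inf]
            )
            total += len(onsets)
            recalled += sum(np.min(np.abs(anchors - o)) <= 4.0 for o in onsets)
        assert recalled / total >= floor
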