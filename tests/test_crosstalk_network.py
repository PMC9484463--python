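"""coreg scoring, motif typing, network building and crosstalk typing."""

import numpy as np
import pytest

from conftest import profile
from mircrosstalk.crosstalk_network import (
    CoregMotif,
    CrosstalkEdge,
    build_network,
    coreg_score,
    crosstalk_type,
    motif_coreg_type,
    shared_targets,
)

ECOS = [f"e{i}" for i in range(10)]


def _pair(fates_i, fates_j, in_ref_i=True, in_ref_j=True):
    pi = profile("m1", "t", dict(zip(ECOS, fates_i)), in_reference=in_ref_i)
    pj = profile("m2", "t", dict(zip(ECOS, fates_j)), in_reference=in_ref_j)
    return pi, pj


class TestCoregScore:
    def test_identical_profiles_score_one(self):
        pi, pj = _pair("k" * 10, "k" * 10)
        assert coreg_score(pi, pj) == 1.0

    def test_fully_discordant_profiles_score_zero(self):
        pi, pj = _pair("k" * 10, "llll" + "oooooo")
        assert coreg_score(pi, pj) == 0.0

    def test_partial_agreement_fraction(self):
        # joint fates (k,k) x7, (k,l) x2, (l,l) x1; both general fates KL
        pi, pj = _pair("k" * 9 + "l", "k" * 7 + "ll" + "l")
        assert coreg_score(pi, pj) == pytest.approx(0.8)

    def test_kl_pair_with_disjoint_losses_forced_to_zero(self):
        pi, pj = _pair("l" + "k" * 9, "k" * 9 + "l")
        assert coreg_score(pi, pj) == 0.0

    def test_joint_ambiguity_is_not_agreement(self):
        pi, pj = _pair("o" * 9 + "k", "o" * 9 + "k")
        assert coreg_score(pi, pj) == pytest.approx(0.1)

    def test_gained_cluster_modes(self):
        fates = "gg" + "n" * 8
        pi, pj = _pair(fates, fates, in_ref_i=False, in_ref_j=False)
        assert coreg_score(pi, pj, mode="extended") == 1.0
        assert coreg_score(pi, pj, mode="literal") == pytest.approx(0.2)

    def test_gg_disjoint_gains_forced_to_zero_in_extended_mode(self):
        pi, pj = _pair(
            "g" + "n" * 9, "n" * 9 + "g", in_ref_i=False, in_ref_j=False
        )
        assert coreg_score(pi, pj, mode="extended") == 0.0

    def test_empty_universe_drops_motif(self):
        pi = profile("m1", "t", {"e1": "k"})
        pj = profile("m2", "t", {"e2": "k"})
        assert coreg_score(pi, pj) is None

    def test_symmetry_and_bounds_on_random_profiles(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            in_ref = bool(rng.integers(0, 2))
            alphabet = list("klo") if in_ref else list("gon")
            fi = rng.choice(alphabet, size=10)
            fj = rng.choice(alphabet, size=10)
            if in_ref:
                fi[0] = fj[0] = "k"  # keep the general fate well-defined
            else:
                fi[0] = fj[0] = "g"
            pi, pj = _pair("".join(fi), "".join(fj), in_ref, in_ref)
            s_ij = coreg_score(pi, pj)
            s_ji = coreg_score(pj, pi)
            assert s_ij == s_ji
            assert 0.0 <= s_ij <= 1.0


def oracle_coreg(pi, pj, mode="extended"):
    """Brute-force joint-fate counter, independent of the implementation."""
    shared = sorted(set(pi.fates) & set(pj.fates))
    if not shared:
        return None
    pairs = [(pi.fates[e], pj.fates[e]) for e in shared]
    n_l = sum(1 for a, b in pairs if (a, b) == ("l", "l"))
    n_g = sum(1 for a, b in pairs if (a, b) == ("g", "g"))
    gi, gj = pi.general_fate, pj.general_fate
    if gi == "KL" and gj == "KL" and n_l == 0:
        return 0.0
    if mode == "extended" and gi == "G" and gj == "G" and n_g == 0:
        return 0.0
    good = {("k", "k"), ("l", "l"), ("g", "g")}
    if mode == "extended":
        good.add(("n", "n"))
    return sum(1 for p in pairs if p in good) / len(pairs)


@pytest.mark.parametrize("mode", ["extended", "literal"])
def test_oracle_equivalence_on_random_profile_pairs(mode):
    rng = np.random.default_rng(17)
    n_checked = 0
    while n_checked < 1000:
        in_ref = bool(rng.integers(0, 2))
        alphabet = list("klo") if in_ref else list("gon")
        n_eco = int(rng.integers(3, 25))
        fi = "".join(rng.choice(alphabet, size=n_eco))
        fj = "".join(rng.choice(alphabet, size=n_eco))
        pi = profile("m1", "t", dict(zip(ECOS * 3, fi)), in_reference=in_ref)
        pj = profile("m2", "t", dict(zip(ECOS * 3, fj)), in_reference=in_ref)
        try:
            pi.general_fate, pj.general_fate
        except ValueError:
            continue  # gained nowhere: no general fate, no motif
        assert coreg_score(pi, pj, mode=mode) == oracle_coreg(pi, pj, mode)
        n_checked += 1


class TestMotifType:
    @pytest.mark.parametrize(
        "fates,expected",
        [
            (("K", "K"), "ss"),
            (("K", "KL"), "sd"),
            (("KL", "K"), "sd"),
            (("KL", "KL"), "dd"),
            (("G", "G"), "dd"),
            (("K", "G"), "excluded"),
            (("KL", "G"), "excluded"),
            (("L", "K"), "excluded"),
        ],
    )
    def test_mapping(self, fates, expected):
        assert motif_coreg_type(*fates) == expected


class TestSharedTargets:
    def test_counts(self):
        profiles = {}
        for t in ("t1", "t2", "t3"):
            profiles[("m1", t)] = profile("m1", t, {"e": "k"})
            profiles[("m2", t)] = profile("m2", t, {"e": "k"})
        profiles[("m3", "t9")] = profile("m3", "t9", {"e": "k"})
        assert shared_targets(profiles, "m1", "m2") == {"t1", "t2", "t3"}
        assert shared_targets(profiles, "m1", "m3") == set()
        with pytest.raises(ValueError):
            shared_targets(profiles, "m1", "m1")


class TestBuildNetwork:
    def _profiles(self):
        profiles = {}
        # planted co-inherited pair: losses together in e0-e1 -> coreg 1.0
        for m in ("m1", "m2"):
            profiles[(m, "t1")] = profile(m, "t1", dict(zip(ECOS, "ll" + "k" * 8)))
        # discordant pair: coreg 0.3
        profiles[("m3", "t2")] = profile("m3", "t2", dict(zip(ECOS, "lll" + "k" * 3 + "llll")))
        profiles[("m4", "t2")] = profile("m4", "t2", dict(zip(ECOS, "lll" + "l" * 3 + "kkkk")))
        return profiles

    def test_threshold_filters_discordant_pair(self):
        profiles = self._profiles()
        pi, pj = profiles[("m3", "t2")], profiles[("m4", "t2")]
        assert coreg_score(pi, pj) == pytest.approx(0.3)
        net = build_network(profiles, threshold=0.85)
        assert set(net.edges) == {frozenset(("m1", "m2"))}
        assert net.deleted_pairs == {frozenset(("m3", "m4"))}
        assert len(net.unfiltered_pairs) == 2

    def test_zero_threshold_keeps_everything(self):
        net = build_network(self._profiles(), threshold=0.0)
        assert len(net.edges) == 2 and not net.deleted_pairs

    def test_score_equal_to_threshold_survives(self):
        net = build_network(self._profiles(), threshold=1.0)
        assert set(net.edges) == {frozenset(("m1", "m2"))}


class TestCrosstalkType:
    def _edge(self, type_counts):
        motifs = [
            CoregMotif("a", "b", f"t{i}{ctype}", 1.0, ctype, 10)
            for ctype, n in type_counts.items()
            for i in range(n)
        ]
        return CrosstalkEdge("a", "b", motifs)

    def test_majority_dd(self):
        assert crosstalk_type(self._edge({"dd": 16, "ss": 2})) == "DD"

    def test_majority_ss(self):
        assert crosstalk_type(self._edge({"ss": 12, "sd": 1})) == "SS"

    def test_no_strict_majority_is_unclassified(self):
        assert crosstalk_type(self._edge({"ss": 5, "sd": 5})) == "unclassified"

    def test_excluded_cannot_become_a_type(self):
        assert crosstalk_type(self._edge({"excluded": 9, "ss": 1})) == "unclassified"

    def test_empty_edge_rejected(self):
        with pytest.raises(ValueError):
            crosstalk_type(CrosstalkEdge("a", "b", []))
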