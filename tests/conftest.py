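"""Shared fixtures: small hand-built panels and one session-scoped default run."""

from __future__ import annotations

import pytest

from mircrosstalk.crosstalk_network import build_network
from mircrosstalk.fate_engine import FateProfile, build_fate_profiles
from mircrosstalk.pipeline import predict_panel
from mircrosstalk.population_genomes import filter_singletons
from mircrosstalk.synthetic_fixtures import FixtureSpec, generate_panel


def profile(mirna, target, fates, in_reference=True):
    """Terse FateProfile constructor for unit tests."""
    return FateProfile(key=(mirna, target), fates=dict(fates), in_reference=in_reference)


@pytest.fixture(scope="session")
def default_truth():
    """The default synthetic study panel (100 ecotypes, 30 miRNAs)."""
    return generate_panel(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def default_run(default_truth):
    """Profiles and the 0.85-threshold network for the default panel."""
    panel = default_truth.panel
    panel.variants = filter_singletons(panel.variants)
    ref, eco, discarded = predict_panel(panel)
    profiles = build_fate_profiles(ref["A"], ref["B"], eco, discarded)
    network = build_network(profiles, threshold=0.85)
    return {
        "truth": default_truth,
        "ref": ref,
        "eco": eco,
        "discarded": discarded,
        "profiles": profiles,
        "network": network,
    }


@pytest.fixture()
def tiny_truth():
    """A fast panel for file/pipeline round-trips."""
    spec = FixtureSpec(
        seed=3,
        n_ecotypes=30,
        n_mirnas=10,
        n_transcripts=12,
        n_planted_coop_pairs=3,
        n_discordant_pairs=2,
        planted_kind_cycle=("ss", "sd", "dd_loss"),
        cluster_size=4,
        n_singletons=5,
        n_indels=2,
    )
    return generate_panel(spec)
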