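import numpy as np
import pytest

from dctmosaic import (
    ParentPairConfig,
    TransferConfig,
    generate_parent_pair,
    simulate_transconjugant,
)


@pytest.fixture(scope="session")
def small_pair():
    """A 100-kb parent pair at the divergent-pair density (0.01/bp)."""
    cfg = ParentPairConfig(length_bp=100_000, snv_density=0.01, seed=7)
    return generate_parent_pair(cfg)


@pytest.fixture(scope="session")
def small_cross(small_pair):
    """A transconjugant with 4 planted donor segments on the small pair."""
    recipient, donor, _ = small_pair
    cfg = TransferConfig(
        n_segments=4,
        segment_length_dist=("log-uniform", 2_000, 20_000),
        min_gap_bp=1_000,
        seed=3,
    )
    tc, truth = simulate_transconjugant(recipient, donor, cfg)
    return recipient, donor, tc, truth


def hamming_identity(window: str, parent: str) -> float:
    """Independent brute-force per-position identity (N = mismatch)."""
    assert len(window) == len(parent)
    matches = sum(
        1 for a, b in zip(window, parent) if a == b and a != "N"
    )
    return matches / len(window)


def truth_majority_vote(tc_seq, rec_seq, don_seq, start, end):
    """Per-window majority vote over informative sites, or None on a tie.

    Informative sites are positions where the parents differ; each votes
    for the parent whose base the transconjugant carries.
    """
    rec_votes = don_votes = 0
    for i in range(start, end):
        if rec_seq[i] != don_seq[i]:
            if tc_seq[i] == don_seq[i]:
                don_votes += 1
            elif tc_seq[i] == rec_seq[i]:
                rec_votes += 1
    n = rec_votes + don_votes
    if n == 0 or rec_votes == don_votes:
        return None, n
    return ("recipient" if rec_votes > don_votes else "donor"), n
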