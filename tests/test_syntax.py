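"""Movement syntax: strokelet parsing, grouping, bottleneck words."""

import numpy as np
import pytest

from scribblekit import syntax, synthgen


@pytest.fixture(scope="module")
def syntax_record():
    traj, truth = synthgen.gen_syntax_trajectory(n_strokes=400, seed=0)
    return traj, truth


def test_parse_strokelets_alternate(syntax_record):
    traj, truth = syntax_record
    lets = syntax.parse_strokelets(traj)
    assert len(lets) > 100
    flags = [s.accel for s in lets]
    assert all(a != b for a, b in zip(flags[:-1], flags[1:]))


def test_descriptor_shape(syntax_record):
    traj, _ = syntax_record
    lets = syntax.parse_strokelets(traj)
    d = syntax.describe(lets[3])
    assert d.angles.shape == (10,)
    assert isinstance(d.accel, (bool, np.bool_))


def test_grouping_is_pure_wrt_words(syntax_record):
    traj, truth = syntax_record
    lets = syntax.parse_strokelets(traj)
    desc = [syntax.describe(s) for s in lets]
    labels = syntax.group_strokelets(desc, k_range=(6, 6), seed=0)
    # word identity of each strokelet from its midpoint sample
    mids = [(s.start + s.stop) // 2 for s in lets]
    words = truth["word"][mids]
    # each group should contain strokelets of a single word
    purity = []
    for g in np.unique(labels):
        w = words[labels == g]
        purity.append(np.bincount(w).max() / len(w))
    assert np.mean(purity) > 0.95


def test_ib_recovers_planted_block_matrix():
    # 24 groups, 12 planted clusters of 2; each cluster deterministically
    # transitions to the next (cyclically), so merging within planted
    # blocks loses nothing and any other merge loses information
    counts = np.zeros((24, 24))
    for g in range(24):
        blk = g // 2
        nxt = (blk + 1) % 12
        for tgt in (2 * nxt, 2 * nxt + 1):
            counts[g, tgt] = 30.0
    model = syntax.ib_cluster(counts, n_clusters=12)
    assign = model.ib_clusters
    # exact recovery of the 12 planted blocks
    for blk in range(12):
        assert assign[2 * blk] == assign[2 * blk + 1]
    assert len(np.unique(assign)) == 12
    assert model.retention == pytest.approx(1.0, abs=1e-9)


def test_ib_rejects_too_many_clusters():
    counts = np.eye(5)
    with pytest.raises(ValueError):
        syntax.ib_cluster(counts, n_clusters=10)


def test_extract_cycles_finds_planted_words():
    # two 3-cycles joined by one weak gateway edge
    m = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)]:
        m[a, b] = 0.9
    m[2, 3] = 0.3
    out = syntax.extract_cycles(m, threshold=0.2)
    assert out["n_words"] == 2
    assert sorted(map(sorted, out["words"])) == [[0, 1, 2], [3, 4, 5]]
    assert any(g["from_cluster"] == 2 and g["to_cluster"] == 3
               for g in out["gateways"])


def test_full_syntax_pipeline_recovers_three_words(syntax_record):
    traj, truth = syntax_record
    lets = syntax.parse_strokelets(traj)
    desc = [syntax.describe(s) for s in lets]
    labels = syntax.group_strokelets(desc, k_range=(6, 6), seed=0)
    model = syntax.ib_cluster(syntax.transition_model(labels), n_clusters=12)
    out = syntax.extract_cycles(model.cluster_matrix)
    assert out["n_words"] == truth["n_words"] == 3
    assert syntax.information_retention(model) > 0.9
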