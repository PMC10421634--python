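import numpy as np
import pytest

from ethokit import (
    compute_features,
    default_skeleton,
    generate_markov_labels,
    make_repertoire,
    normalize_features,
    normalize_pose,
    pca_reduce,
    render_poses,
)


@pytest.fixture(scope="session")
def skeleton():
    return default_skeleton()


@pytest.fixture(scope="session")
def repertoire(skeleton):
    return make_repertoire(skeleton=skeleton, seed=11)


@pytest.fixture(scope="session")
def rendered_session(skeleton, repertoire):
    """A clean 5000-frame synthetic session with its ground truth."""
    labels, gt = generate_markov_labels(repertoire, 5000, seed=21)
    seq = render_poses(labels, skeleton, repertoire, noise_sd=0.01, seed=22)
    return seq, gt


@pytest.fixture(scope="session")
def session_features(skeleton, rendered_session):
    """Normalized 23-dim features + PCA scores of the rendered session."""
    seq, gt = rendered_session
    norm = normalize_pose(seq, skeleton)
    fm = normalize_features(compute_features(norm, seq, skeleton))
    scores, _ = pca_reduce(fm)
    return fm, scores, gt
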