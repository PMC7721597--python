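import numpy as np
import pytest

from kneeseg.data import SlicePair
from kneeseg.label_codec import DEFAULT_SCHEME, TissueMask, encode_labels
from kneeseg.phantom import PhantomConfig, generate_subject, subject_seeds


@pytest.fixture(scope="session")
def phantom_cohort():
    """Default-condition phantom cohort: 8 training + 2 held-out subjects."""
    cfg = PhantomConfig(seed=1)
    seeds = subject_seeds(cfg)
    subjects = {f"subj{i:02d}": generate_subject(cfg, seeds[i],
                                                 subject_id=f"subj{i:02d}")
                for i in range(cfg.n_subjects)}
    ids = sorted(subjects)
    train = [p for sid in ids[:8] for p in subjects[sid]]
    test = [p for sid in ids[8:] for p in subjects[sid]]
    return cfg, train, test


def make_square_pairs(n: int, size: int = 32, subject_id: str = "s00",
                      seed: int = 0) -> list[SlicePair]:
    """Tiny synthetic pairs: a bright square labelled as femur, for fast tests."""
    rng = np.random.default_rng(seed)
    pairs = []
    for k in range(n):
        mask = np.zeros((size, size), dtype=bool)
        c = size // 2 + int(rng.integers(-3, 4))
        r = size // 4
        mask[c - r:c + r, c - r:c + r] = True
        source = np.where(mask, 0.8, 0.1) + rng.normal(0, 0.02, (size, size))
        label = encode_labels(
            {"femur": TissueMask(mask, (1.0, 1.0), "femur")},
            scheme=DEFAULT_SCHEME, subject_id=subject_id, slice_index=k)
        pairs.append(SlicePair(source=np.clip(source, 0, 1), label=label))
    return pairs
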