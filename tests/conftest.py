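import numpy as np
import pytest

from ethosyntax.ethogram import BoutEthogram
from ethosyntax.markov import build_state_space


def make_bouts(actions, durations, categories=None, **kw):
    return BoutEthogram(
        actions=np.asarray(actions),
        durations=np.asarray(durations, dtype=float),
        categories=None if categories is None else np.asarray(categories, dtype=int),
        **kw,
    )


def make_toy_fly(seed, pool=None, catmap=None, n_bins=3):
    """A ~30-bout fly with a FIXED bout multiset (actions x categories) and a
    seed-dependent order with no same-action adjacency.

    Sharing one multiset across flies makes the within-fly permutation nulls'
    infinite-permutation limit coincide exactly with the cohort-pooled
    analytic null.
    """
    r = np.random.default_rng(seed)
    if pool is None:
        pool = ["f"] * 10 + ["h"] * 8 + ["a"] * 7 + ["wk"] * 5
    if catmap is None:
        catmap = {
            "f": [0] * 4 + [1] * 3 + [2] * 3,
            "h": [0] * 3 + [1] * 3 + [2] * 2,
            "a": [0] * 2 + [1] * 3 + [2] * 2,
            "wk": [0] * 2 + [1] * 2 + [2] * 1,
        }
    out = list(pool)
    r.shuffle(out)
    for i in range(1, len(out)):  # repair same-action adjacencies
        if out[i] == out[i - 1]:
            for j in range(len(out)):
                if (
                    out[j] != out[i]
                    and (j == 0 or out[j - 1] != out[i])
                    and (j + 1 >= len(out) or out[j + 1] != out[i])
                ):
                    out[i], out[j] = out[j], out[i]
                    break
    assert all(out[i] != out[i - 1] for i in range(1, len(out)))
    used = {a: 0 for a in catmap}
    cats = []
    for a in out:
        cats.append(catmap[a][used[a]])
        used[a] += 1
    durs = r.uniform(0.2, 3.0, len(out))
    return make_bouts(out, durs, cats, fly_id=f"toy-{seed}")


@pytest.fixture
def toy_cohort():
    """3 flies x 30 bouts, shared multiset, 4 actions x 3 categories."""
    return [make_toy_fly(s) for s in (1, 2, 3)]


@pytest.fixture
def toy_space():
    return build_state_space(("f", "h", "a", "wk"), 3)
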