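import itertools

import numpy as np
import pandas as pd
import pytest

from svbn.cohort import DiscreteCohort
from svbn.model import DAGStructure
from svbn.synthetic import build_preset_network


@pytest.fixture
def collider_net():
    """A -> C <- B with P(C=t | A=B=t) = 0.9, else 0.1; roots fair."""
    return build_preset_network("collider_test")


@pytest.fixture
def independent_net():
    return build_preset_network("independent_test")


def make_discrete(columns: dict[str, list[str]], states=("a", "b")) -> DiscreteCohort:
    """Small hand-written discrete cohort."""
    frame = pd.DataFrame(columns)
    return DiscreteCohort(
        data=frame, state_sets={c: tuple(states) for c in frame.columns}
    )


def all_dags(names: list[str], states=("a", "b")):
    """Enumerate every DAG on the given nodes (brute-force oracle)."""
    pairs = list(itertools.combinations(range(len(names)), 2))
    for choice in itertools.product(range(3), repeat=len(pairs)):
        parents: dict[str, list[str]] = {v: [] for v in names}
        for (i, j), c in zip(pairs, choice):
            if c == 1:
                parents[names[j]].append(names[i])
            elif c == 2:
                parents[names[i]].append(names[j])
        try:
            yield DAGStructure(
                nodes=tuple(names),
                state_sets={v: tuple(states) for v in names},
                parents={v: tuple(sorted(p)) for v, p in parents.items()},
            )
        except Exception:
            continue  # cyclic orientation


def random_binary_cohort(names, n, seed, states=("a", "b")) -> DiscreteCohort:
    """Random dependent binary data for structure-search oracle checks."""
    rng = np.random.default_rng(seed)
    cols = {
        v: rng.choice(list(states), size=n, p=[p, 1 - p])
        for v, p in zip(names, rng.uniform(0.2, 0.8, len(names)))
    }
    frame = pd.DataFrame(cols)
    # inject dependence between the last two columns
    if len(names) >= 2:
        flip = rng.random(n) < 0.35
        frame.loc[flip, names[-1]] = frame.loc[flip, names[-2]]
    return DiscreteCohort(
        data=frame, state_sets={v: tuple(states) for v in names}
    )


def markov_class(structure: DAGStructure):
    """(skeleton, v-structures) — the invariants of a Markov equivalence class."""
    skeleton = frozenset(frozenset(e) for e in structure.edges())
    vstructs = set()
    for child in structure.nodes:
        ps = structure.parent_tuple(child)
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                a, b = ps[i], ps[j]
                if (
                    b not in structure.parents.get(a, ())
                    and a not in structure.parents.get(b, ())
                ):
                    vstructs.add((frozenset((a, b)), child))
    return skeleton, frozenset(vstructs)
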