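import numpy as np
import pytest

from tabufs import Dataset


@pytest.fixture
def separable_ds() -> Dataset:
    """Perfectly separable 2-feature dataset: feature 0 carries the label,
    feature 1 is fixed noise."""
    rng = np.random.default_rng(7)
    n = 20
    labels = np.array([1] * 10 + [0] * 10)
    x0 = np.where(labels == 1, 1.0, -1.0) + 0.05 * rng.normal(size=n)
    x1 = rng.normal(size=n)
    return Dataset(np.column_stack([x0, x1]), labels, ["signal", "noise"])


@pytest.fixture
def random_ds() -> Dataset:
    """Labels independent of all five features."""
    rng = np.random.default_rng(11)
    n = 120
    labels = (rng.random(n) < 0.4).astype(int)
    if labels.sum() in (0, n):  # pragma: no cover - seed is fixed
        labels[0] = 1 - labels[0]
    return Dataset(rng.normal(size=(n, 5)), labels, [f"v{j}" for j in range(5)])


def write_csv(path, text: str) -> str:
    path.write_text(text)
    return str(path)


def full_neighborhood(members, m):
    """All add/remove/swap neighbors of a subset, as member tuples."""
    inside = sorted(members)
    outside = [j for j in range(m) if j not in members]
    neighbors = []
    for j in outside:
        neighbors.append(tuple(sorted(inside + [j])))
    for j in inside:
        neighbors.append(tuple(x for x in inside if x != j))
    for j_out in inside:
        for j_in in outside:
            neighbors.append(tuple(sorted([x for x in inside if x != j_out] + [j_in])))
    return neighbors


def is_local_optimum(ds, subset, f_value, cfg, cache=None):
    """Independent full-sweep check: no neighbor has strictly higher f."""
    from tabufs import evaluate

    for nb in full_neighborhood(subset.members, ds.m):
        if evaluate(ds, nb, cfg, cache)[1] > f_value:
            return False
    return True
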