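import numpy as np
import pytest

import lactoclust as lc


def make_record(animal_id, dims, values, parity=2):
    """Build a LactationRecord from parallel DIM/value sequences."""
    return lc.LactationRecord(animal_id, parity, dict(zip(map(int, dims), values)))


def wood_record(animal_id, params=(24.6645, 0.2142, 0.0039), dims=None, parity=2):
    """A noiseless Wood-curve record covering DIM 5..300 by default."""
    if dims is None:
        dims = np.arange(5, 301)
    values = lc.eval_model("wood", params, np.asarray(dims, dtype=float))
    return make_record(animal_id, dims, values, parity=parity)


@pytest.fixture
def filter_fixture_herd():
    """10-lactation herd with hand-designed filter outcomes.

    4 complete records (kept), 2 starting at DIM 25 (late start),
    1 with a single missing day at DIM 40 (early gap), 3 with a 15-day
    gap at DIM 150..164 (long mid-lactation gap).
    """
    herd = [wood_record(f"ok{i}") for i in range(4)]
    herd += [wood_record(f"late{i}", dims=np.arange(25, 301)) for i in range(2)]
    gap40 = [d for d in range(5, 301) if d != 40]
    herd.append(wood_record("gap40", dims=gap40))
    gap150 = [d for d in range(5, 301) if not 150 <= d <= 164]
    herd += [wood_record(f"gap150_{i}", dims=gap150) for i in range(3)]
    return herd


@pytest.fixture(scope="session")
def planted_herd():
    """90 lactations from 3 well-separated archetypes, 2% noise, no
    missingness, plus the ground-truth archetype labels."""
    arch = lc.default_archetypes()
    mix = (
        (arch["typical"], 1 / 3),
        (arch["flat_primiparous"], 1 / 3),
        (arch["undulating"], 1 / 3),
    )
    herd = lc.HerdSpec(n_lactations=90, archetype_mix=mix, noise_cv=0.02, seed=7)
    records, truth = lc.generate_herd(herd)
    return records, truth


@pytest.fixture(scope="session")
def planted_matrix(planted_herd):
    records, truth = planted_herd
    report = lc.filter_lactations(records)
    matrix = lc.build_curve_matrix(report.kept)
    id2arch = dict(zip(truth.animal_id, truth.archetype))
    true_labels = [id2arch[i] for i in matrix.ids]
    return matrix, true_labels
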