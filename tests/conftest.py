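import numpy as np
import pandas as pd
import pytest

from crypteqtl import ExpressionMatrix, GenotypeMatrix, MarkerMap


def make_expression(values, treatments=None, strains=None, spots=None, ages=None):
    """Build a small ExpressionMatrix around a spots x samples array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_spots, n_samples = values.shape
    spots = spots or [f"s{i}" for i in range(n_spots)]
    samples = [f"sample{j}" for j in range(n_samples)]
    strains = strains or [f"RIL{j:03d}" for j in range(n_samples)]
    treatments = treatments or ["empty_vector"] * n_samples
    meta = pd.DataFrame(
        {"strain": strains, "treatment": treatments},
        index=pd.Index(samples, name="sample"),
    )
    if ages is not None:
        meta["age_h"] = ages
    return ExpressionMatrix(
        spots=tuple(spots), samples=tuple(samples), values=values, metadata=meta
    )


def make_genotypes(calls, positions=None, chromosomes=None, strains=None):
    """Build a GenotypeMatrix from a 0/1/-1 array on one or more chromosomes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_strains, n_markers = calls.shape
    positions = positions if positions is not None else np.arange(1, n_markers + 1) * 100_000
    chromosomes = (
        chromosomes
        if chromosomes is not None
        else np.array(["I"] * n_markers, dtype=object)
    )
    mm = MarkerMap(
        marker_ids=tuple(f"m{j}" for j in range(n_markers)),
        chromosome=np.asarray(chromosomes, dtype=object),
        position_bp=np.asarray(positions),
    )
    strains = strains or [f"RIL{j:03d}" for j in range(n_strains)]
    return GenotypeMatrix(strains=tuple(strains), markers=mm, calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
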