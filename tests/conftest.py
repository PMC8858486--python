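import numpy as np
import pandas as pd
import pytest

from coloc3d import (SimulationParams, map_features, pairwise_distances,
                     simulate_genome3d)


@pytest.fixture(scope="session")
def small_genome():
    """A small simulated genome shared across tests: 6 chromosomes of
    150 kb, ~450 genes, ~100k pairwise distances."""
    params = SimulationParams(n_chromosomes=6, chromosome_lengths=[150_000] * 6,
                              anchor_spacing_mean=10_000, gene_spacing=2_000,
                              seed=11)
    model, features = simulate_genome3d(params)
    coords = map_features(model, features)
    dset = pairwise_distances(coords)
    return {"params": params, "model": model, "features": features,
            "coords": coords, "dset": dset}


@pytest.fixture()
def toy_model_df():
    """Two straight-line chromosomes with anchors every 1000 bp."""
    rows = []
    for chrom, z in (("chrA", 0.0), ("chrB", 0.5)):
        for k in range(5):
            rows.append((chrom, 1000 * (k + 1), float(k), 2.0, z))
    return pd.DataFrame(rows, columns=["chromosome", "position", "x", "y", "z"])


@pytest.fixture()
def toy_model(toy_model_df, tmp_path):
    from coloc3d import read_model3d
    path = tmp_path / "model.tsv"
    toy_model_df.to_csv(path, sep="\t", index=False, header=False)
    return read_model3d(path)


def write_tsv(path, text):
    path.write_text(text)
    return path
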