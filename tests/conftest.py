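"""Shared fixtures: seeded synthetic bundles and window helpers."""

from __future__ import annotations

import numpy as np
import pytest

from polyascan import synthetic_data as sd
from polyascan.genome_io import Genome


@pytest.fixture(scope="session")
def bundle() -> sd.SyntheticGenomeBundle:
    """Default-scale bundle: 2 x 50 kb, 40 functional + 40 decoy sites."""
    return sd.generate_genome(sd.SyntheticGenomeConfig(seed=11))


@pytest.fixture(scope="session")
def large_bundle() -> sd.SyntheticGenomeBundle:
    """Bundle with 250 functional + 250 decoy sites for metric-level checks."""
    return sd.generate_genome(
        sd.SyntheticGenomeConfig(
            n_chroms=2,
            chrom_length=80_000,
            n_true_sites=250,
            n_decoy_sites=250,
            seed=19,
        )
    )


def site_window(genome: Genome, chrom: str, pos: int) -> str:
    return genome[chrom][pos - 50 : pos + 51]


@pytest.fixture(scope="session")
def labeled_windows(large_bundle):
    """(windows, labels): functional (1) vs decoy (0) 101-nt windows."""
    windows, labels = [], []
    for s in large_bundle.polya_sites:
        windows.append(site_window(large_bundle.genome, s.chrom, s.start))
        labels.append(1)
    for s in large_bundle.decoy_sites:
        windows.append(site_window(large_bundle.genome, s.chrom, s.start))
        labels.append(0)
    return windows, np.array(labels)


@pytest.fixture(scope="session")
def labeled_embeddings(labeled_windows):
    windows, labels = labeled_windows
    X = np.array([sd.toy_embedder(w) for w in windows])
    return X, labels
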