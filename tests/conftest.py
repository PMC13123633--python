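import numpy as np
import pandas as pd
import pytest

from wolfscan.genotype_qc import GenotypeMatrix


def build_matrix(dosages, depth=None, quality=None, chrom=None, pos=None,
                 ref=None, alt=None, annotation=None, populations=None,
                 masked=False, site_filtered=False):
    """Assemble a GenotypeMatrix from plain lists for toy tests."""
    dosages = np.asarray(dosages, dtype=np.int16)
    n_sites, n_samples = dosages.shape
    depth = np.asarray(depth if depth is not None else np.full(dosages.shape, 30))
    quality = np.asarray(quality if quality is not None else np.full(dosages.shape, 99))
    sites = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["chr1"] * n_sites,
            "pos": pos if pos is not None else list(range(1, n_sites + 1)),
            "ref": ref if ref is not None else ["A"] * n_sites,
            "alt": alt if alt is not None else ["G"] * n_sites,
        }
    )
    if annotation is not None:
        sites["annotation"] = annotation
    populations = populations if populations is not None else ["focal"] * n_samples
    samples = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n_samples)], "population": populations}
    )
    return GenotypeMatrix(
        sites=sites, dosages=dosages, depth=depth, quality=quality,
        samples=samples, masked=masked, site_filtered=site_filtered,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
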