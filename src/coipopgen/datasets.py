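"""Bundled published summary tables for the seven-population P. sinensis
COI survey this package reanalyzes.

Only printed summary tables ship with the package (population-level K2P
distances, sudden-expansion parameters, sampling metadata). The underlying
674-bp alignments are public under GenBank accessions MT884019-MT884059
(41 haplotype sequences); together with the haplotype-by-population count
table they reconstruct the original 326-individual dataset, which can then
be fed to the pipeline via ``haplotypes.read_haplotype_table`` and
``haplotypes.expand_to_alignment``. The package never fetches them itself.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .distances import DistanceMatrix

GENBANK_ACCESSIONS = "MT884019-MT884059"


def _path(name: str):
    return resources.files("coipopgen.data").joinpath(name)


def load_ds_matrix() -> DistanceMatrix:
    """Published between-population K2P distance (Ds) matrix."""
    with resources.as_file(_path("psinensis_coi_ds_matrix.csv")) as p:
        return DistanceMatrix.from_csv(p)


def load_expansion_parameters() -> pd.DataFrame:
    """Published sudden-expansion fits (tau, theta0, theta1, SSD, HRI)."""
    with resources.as_file(_path("psinensis_coi_expansion.csv")) as p:
        return pd.read_csv(p)


def load_sampling_metadata() -> pd.DataFrame:
    """Sampling localities, coordinates and per-population sample sizes."""
    with resources.as_file(_path("psinensis_coi_samples.csv")) as p:
        return pd.read_csv(p)
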