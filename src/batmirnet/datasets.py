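"""Bundled reference tables for the vampire-bat study system.

Small curated TSVs shipped with the package: the annotation transfers for
the 29 newly named uncharacterized proteins, the IRF-family identity matrix
across 13 mammals, the 19 novel miRNA candidates with their thermodynamic
descriptors, the top-20 high-confidence miRNA-target interactions, and the
per-node entropy-knockout table of the regulatory network.  They serve as
worked inputs for the filtering and reporting operations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("batmirnet") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", **kwargs)


def ucp_annotation_transfers() -> pd.DataFrame:
    """29 uncharacterized-protein annotation transfers (accession, homolog
    species, transferred annotation, percent identity, E-value)."""
    return _load("ucp_annotation_transfers.tsv")


def irf_identity_matrix() -> pd.DataFrame:
    """Percent identity of the eight interferon regulatory factors between
    the vampire bat and 13 other mammals (species-indexed)."""
    return _load("irf_identity_matrix.tsv", index_col=0)


def novel_mirna_candidates() -> pd.DataFrame:
    """The 19 retained novel miRNA candidates with length, mismatch count,
    minimum free energy (kcal/mol) and ensemble diversity."""
    return _load("novel_mirna_candidates.tsv")


def mirna_target_interactions() -> pd.DataFrame:
    """Top-20 high-confidence miRNA-target interactions with binding
    energies (kcal/mol) and validated accession ids."""
    return _load("mirna_target_interactions.tsv")


def entropy_knockout_table() -> pd.DataFrame:
    """Per-node knockout entropies of the regulatory network (degree, degree
    probability, original/new entropy, entropy change)."""
    return _load("entropy_knockout_table.tsv")
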