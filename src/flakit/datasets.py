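"""Packaged reference tables for the *Populus trichocarpa* FLA family.

``ptrfla_loci`` transcribes the published 35-gene locus table (symbol,
locus id, genomic position, gene/ORF/protein lengths, MW, pI);
``ptrfla_pairs`` transcribes the 12 duplicate gene pairs with their
published Ka, Ks, Ka/Ks and divergence-time estimates.
"""

from __future__ import annotations

from importlib import resources
from typing import List

import pandas as pd

from .io import parse_locus_table
from .records import GeneLocus


def _data_path(name: str):
    return resources.files("flakit.data").joinpath(name)


def load_ptrfla_loci() -> List[GeneLocus]:
    """The 35 PtrFLA gene loci as validated :class:`GeneLocus` records."""
    with resources.as_file(_data_path("ptrfla_loci.tsv")) as p:
        return parse_locus_table(p)


def load_ptrfla_locus_table() -> pd.DataFrame:
    """The raw locus table as a DataFrame (includes localization column)."""
    with resources.as_file(_data_path("ptrfla_loci.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_ptrfla_pairs() -> pd.DataFrame:
    """The 12 PtrFLA duplicate pairs with published Ka, Ks, Ka/Ks and MYA."""
    with resources.as_file(_data_path("ptrfla_pairs.tsv")) as p:
        return pd.read_csv(p, sep="\t")
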