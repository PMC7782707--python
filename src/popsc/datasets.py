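"""Small bundled reference tables.

The ligand-receptor fixture is a compact curated list of well-known
single-gene ligand-receptor couples (cytokines, growth factors, ECM
components and their receptors) sufficient for testing the communication
stage; any user-supplied TSV with ligand/receptor columns works the same way.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def lr_pairs_path() -> Path:
    """Path of the bundled ligand-receptor pair table (TSV)."""
    return Path(resources.files("popsc").joinpath("data/lr_pairs.tsv"))


def load_lr_pairs():
    """The bundled ligand-receptor pairs as a list of LigandReceptorPair."""
    from popsc.io import read_lr_pairs

    return read_lr_pairs(lr_pairs_path())
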