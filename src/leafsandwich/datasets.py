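"""Packaged reference data: the 36-species trait table and a fixture tree.

The trait table holds species-mean mechanical and anatomical traits for 36
broad-leaved angiosperms (15 herbaceous, 12 deciduous woody, 9 evergreen
woody; 33 families): tensile and bending whole-lamina moduli, their ratio,
lamina thickness, mesophyll fraction alpha, the inverted layer moduli and
bending stiffness per unit width.  Each value is a mean of five replicate
leaves; the tabulated ratio column is the mean of per-replicate ratios, so it
differs slightly from E_B/E_T computed on the species means.

The companion tree is a synthetic family-level phylogeny: tips are the 36
species, topology is a fixed resolution consistent with the species' family
memberships (congeners and confamilials are sisters), and every branch has
unit length, as appropriate when divergence times are unknown.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import dendropy
import pandas as pd

from .comparative import validate_trait_table

__all__ = ["load_table1", "fixture_tree", "TABLE1_SHA256"]

#: checksum of the packaged trait table (integrity guard)
TABLE1_SHA256 = "7a165caebfc36ff7336efca101ac87107d79f6e5dd972a8d55abd489f5e01944"


def _data_path(name: str):
    return resources.files("leafsandwich.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """Load the packaged 36-species trait table.

    Columns: species, family, functional_group (H/D, H/E, W/D, W/E), E_T,
    E_B (MPa), ratio (E_B/E_T, replicate-mean), thickness (mm), alpha
    (fraction), E_f, E_c (MPa), EB_I (N mm^3 per mm width).
    """
    raw = _data_path("table1.csv").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise RuntimeError(
            f"packaged trait table is corrupted (sha256 {digest[:12]}…, "
            f"expected {TABLE1_SHA256[:12]}…)"
        )
    table = pd.read_csv(_data_path("table1.csv").open("r"))
    validate_trait_table(table)
    if len(table) != 36:
        raise RuntimeError(f"expected 36 species, found {len(table)}")
    return table


def fixture_tree() -> dendropy.Tree:
    """Load the packaged family-level species tree (rooted, unit branches)."""
    tree = dendropy.Tree.get(
        data=_data_path("species_tree.nwk").read_text(), schema="newick"
    )
    return tree
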