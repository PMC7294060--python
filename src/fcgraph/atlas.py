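"""Node atlas handling: loading, validation, and functional-system partition.

Nodes are the 264 putative functional areas of Power et al. (10 mm spheres
spanning cortex, subcortical structures and cerebellum), partitioned into 12
non-overlapping functional systems; 32 nodes carry no system assignment.
Five networks are analyzed: the *global* network (all 232 assigned nodes)
and the four largest systems -- default mode (DMN), fronto-parietal task
control (FPCN), hand somatosensory-motor (HSMN) and visual (VN).  Smaller
systems are not analyzed separately because meaningful graph statistics
need a minimum of ~20 nodes.

The packaged table ``data/power264_synthetic_partition.tsv`` carries the
published MNI coordinates; its node->system assignment is a synthetic block
reconstruction that reproduces the published system *sizes* exactly (58 DMN,
25 FPCN, 30 HSMN, 31 VN, 232 assigned / 32 unassigned) -- the node-level
identity of individual assignments is not used by any computation in this
package, only the membership structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

#: Closed vocabulary: the 12 named functional systems plus the unassigned bucket.
SYSTEMS = (
    "Sensory/somatomotor Hand",
    "Sensory/somatomotor Mouth",
    "Cingulo-opercular Task Control",
    "Auditory",
    "Default mode",
    "Memory retrieval",
    "Visual",
    "Fronto-parietal Task Control",
    "Salience",
    "Subcortical",
    "Ventral attention",
    "Dorsal attention",
)
UNASSIGNED = "unassigned"

#: Analyzed networks and the system label each one collects.
NETWORK_SYSTEMS = {
    "DMN": "Default mode",
    "FPCN": "Fronto-parietal Task Control",
    "HSMN": "Sensory/somatomotor Hand",
    "VN": "Visual",
}
NETWORK_NAMES = ("global", "DMN", "FPCN", "HSMN", "VN")

#: Minimum node count for a meaningful graph-theoretical analysis.
MIN_NETWORK_NODES = 20

REQUIRED_COLUMNS = ("node_id", "x", "y", "z", "system")


class AtlasError(ValueError):
    """Raised when an atlas table violates the format or its invariants."""


@dataclass(frozen=True)
class NodeAtlas:
    """Validated node table: integer ids, MNI mm coordinates, system labels."""

    table: pd.DataFrame = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def systems(self) -> pd.Series:
        return self.table["system"]

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(float)

    def nodes_with_system(self, system: str) -> np.ndarray:
        return self.table.index[self.table["system"] == system].to_numpy()


@dataclass(frozen=True)
class NetworkDefinition:
    """A named analysis network and its member nodes (positional indices)."""

    name: str
    member_nodes: np.ndarray

    @property
    def size(self) -> int:
        return len(self.member_nodes)


def _validate_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AtlasError(f"atlas table is missing required columns: {missing}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    dup = df["node_id"][df["node_id"].duplicated()]
    if len(dup):
        raise AtlasError(f"duplicate node_id values at rows {dup.index.tolist()}: {dup.tolist()}")
    for col in ("x", "y", "z"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise AtlasError(f"non-numeric coordinate in column {col!r} at row {row}")
        df[col] = pd.to_numeric(df[col])
    vocab = set(SYSTEMS) | {UNASSIGNED}
    unknown = df.loc[~df["system"].isin(vocab), "system"]
    if len(unknown):
        row = int(unknown.index[0])
        raise AtlasError(f"unknown system label {unknown.iloc[0]!r} at row {row}")
    # internal indexing is positional/0-based regardless of the file's ids
    df = df.reset_index(drop=True)
    return df


def load_atlas(path) -> NodeAtlas:
    """Load and validate a node atlas from a TSV file.

    Expected header: ``node_id  x  y  z  system`` with coordinates in MNI mm
    and system labels drawn from the closed 12-system vocabulary (or
    ``unassigned``).
    """
    df = pd.read_csv(path, sep="\t")
    return NodeAtlas(_validate_table(df))


def load_packaged_atlas() -> NodeAtlas:
    """Load the packaged 264-node table (published coordinates, reconstructed partition)."""
    ref = resources.files("fcgraph.data") / "power264_synthetic_partition.tsv"
    with resources.as_file(ref) as path:
        atlas = load_atlas(path)
    if atlas.n_nodes != 264:
        raise AtlasError(f"packaged atlas has {atlas.n_nodes} nodes, expected 264")
    return atlas


def build_networks(atlas: NodeAtlas, names=NETWORK_NAMES) -> list[NetworkDefinition]:
    """Partition the atlas into the analyzed networks.

    ``global`` collects every node with an assigned system; each subsystem
    network collects the nodes of one functional system.  Any requested
    network with fewer than 20 members is rejected, following the
    minimum-node recommendation for graph analysis.
    """
    systems = atlas.systems
    defs = []
    for name in names:
        if name == "global":
            members = atlas.table.index[systems != UNASSIGNED].to_numpy()
        else:
            try:
                label = NETWORK_SYSTEMS[name]
            except KeyError:
                raise AtlasError(f"unknown network name {name!r}; expected one of {NETWORK_NAMES}")
            members = atlas.nodes_with_system(label)
        if len(members) < MIN_NETWORK_NODES:
            raise AtlasError(
                f"network {name!r} has {len(members)} nodes; a minimum of "
                f"{MIN_NETWORK_NODES} nodes is required for graph analysis"
            )
        defs.append(NetworkDefinition(name=name, member_nodes=members))
    return defs
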