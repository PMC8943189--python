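"""Default whole-brain parcellation used for connectome matrices.

The node set follows the Desikan-Killiany-Tourville cortical parcellation
(31 regions per hemisphere) extended with 7 subcortical gray-matter
structures per hemisphere (76 gray-matter nodes in total), plus the left and
right cerebellum and a single midline brainstem node: 79 nodes, of which 39
are lateralized per hemisphere (40 with the shared brainstem after the
hemispheric split).
"""

from __future__ import annotations

from .core_io import NodeEntry, NodeTable

# 31 DKT cortical labels (alphabetical, FreeSurfer naming)
DKT_CORTICAL = (
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "transversetemporal",
    "insula",
)

# 7 subcortical gray structures per hemisphere
SUBCORTICAL = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
)

BRAINSTEM_LABEL = "brainstem"

# lateralized region order (per hemisphere): cortical, subcortical, cerebellum
LATERAL_REGIONS = DKT_CORTICAL + SUBCORTICAL + ("cerebellum",)


def _tissue(region: str) -> str:
    if region == "cerebellum":
        return "cerebellar"
    if region in SUBCORTICAL:
        return "subcortical"
    return "cortical"


def default_node_table() -> NodeTable:
    """79-node whole-brain table: left block, right block, brainstem."""
    entries = []
    homolog = {}
    for region in LATERAL_REGIONS:
        entries.append(NodeEntry(f"lh-{region}", "left", _tissue(region)))
    for region in LATERAL_REGIONS:
        entries.append(NodeEntry(f"rh-{region}", "right", _tissue(region)))
        homolog[f"lh-{region}"] = f"rh-{region}"
    entries.append(NodeEntry(BRAINSTEM_LABEL, "midline", "brainstem"))
    return NodeTable(tuple(entries), homolog)


def gray_matter_labels(table: NodeTable) -> list[str]:
    """Cortical + subcortical labels (the parcellation's gray-matter count)."""
    return [e.label for e in table.entries if e.tissue_class in ("cortical", "subcortical")]
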