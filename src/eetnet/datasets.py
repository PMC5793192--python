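"""Published summary tables of the *S. oneidensis* MR-1 EET study.

These constants are the printed inputs that the package's arithmetic
reproduces without access to the original proteomics or interaction
databases: the per-threshold network statistics, the per-network key-protein
columns and their frequency aggregation, the motif calls, and the two active
cluster sizes.
"""

from __future__ import annotations

#: Size of the sharp-decrease and sharp-increase clusters (active proteins).
CLUSTER_DOWN_SIZE = 1012
CLUSTER_UP_SIZE = 811

#: Smallest with-isolates node count across the six active networks (CS_0.9).
MIN_NETWORK_SIZE = 1118

#: Per-threshold statistics of the published integrated networks:
#: (proteins connected, proteins with isolates, PPI interactions,
#:  regulated genes, regulatory interactions, total nodes, total arcs).
NETWORK_STATS: dict[str, tuple[int, int, int, int, int, int, int]] = {
    "CS_0.4": (1636, 1711, 17577, 582, 714, 1873, 35868),
    "CS_0.5": (1577, 1679, 12343, 579, 712, 1815, 25398),
    "CS_0.6": (1483, 1613, 9460, 574, 705, 1728, 19625),
    "CS_0.7": (1366, 1520, 7030, 567, 697, 1617, 14757),
    "CS_0.8": (1162, 1310, 4972, 536, 662, 1408, 10606),
    "CS_0.9": (997, 1118, 3112, 502, 618, 1229, 6842),
}

#: The 22 key active proteins of each thresholded network, in rank order.
KEY_PROTEINS_PER_NETWORK: dict[str, list[str]] = {
    "CS_0.4": [
        "SO_1325", "SO_3292", "SO_0435", "SO_3430", "SO_3440", "SO_1126",
        "SO_3471", "SO_2619", "SO_3432", "SO_4749", "SO_1197", "SO_0603",
        "SO_2411", "SO_1926", "SO_4215", "SO_3441", "SO_1207", "SO_4586",
        "SO_4747", "SO_3639", "SO_0226", "SO_1552",
    ],
    "CS_0.5": [
        "SO_1325", "SO_3292", "SO_3430", "SO_3440", "SO_1126", "SO_0435",
        "SO_3471", "SO_2619", "SO_3432", "SO_4749", "SO_1926", "SO_4215",
        "SO_4747", "SO_0603", "SO_0226", "SO_3209", "SO_0009", "SO_1197",
        "SO_1207", "SO_3441", "SO_4016", "SO_4586",
    ],
    "CS_0.6": [
        "SO_1325", "SO_3292", "SO_1126", "SO_3430", "SO_3471", "SO_0435",
        "SO_3440", "SO_2619", "SO_1207", "SO_3209", "SO_1926", "SO_4747",
        "SO_3432", "SO_4749", "SO_3441", "SO_4586", "SO_0770", "SO_0009",
        "SO_4215", "SO_0226", "SO_0610", "SO_1197",
    ],
    "CS_0.7": [
        "SO_1325", "SO_3292", "SO_3471", "SO_3430", "SO_3209", "SO_1126",
        "SO_0435", "SO_2491", "SO_1926", "SO_3440", "SO_4747", "SO_0226",
        "SO_4215", "SO_4749", "SO_1207", "SO_3432", "SO_2619", "SO_4586",
        "SO_0009", "SO_0228", "SO_2406", "SO_0610",
    ],
    "CS_0.8": [
        "SO_1325", "SO_0226", "SO_1207", "SO_2491", "SO_3471", "SO_3292",
        "SO_1926", "SO_3430", "SO_2406", "SO_1126", "SO_0236", "SO_0009",
        "SO_0610", "SO_3209", "SO_0435", "SO_2780", "SO_0237", "SO_4747",
        "SO_0608", "SO_0425", "SO_2619", "SO_1473",
    ],
    "CS_0.9": [
        "SO_0228", "SO_1325", "SO_2491", "SO_0226", "SO_0009", "SO_1207",
        "SO_2912", "SO_3292", "SO_0610", "SO_1677", "SO_3471", "SO_0237",
        "SO_3207", "SO_4428", "SO_3209", "SO_2619", "SO_1629", "SO_3210",
        "SO_0247", "SO_3639", "SO_3430", "SO_0435",
    ],
}

#: The published top-20 frequency ranking: protein id -> (name, frequency).
TOP20_KEY_PROTEINS: dict[str, tuple[str, int]] = {
    "SO_0226": ("RpsL", 6),
    "SO_0435": ("HemE", 6),
    "SO_1207": ("RpsO", 6),
    "SO_1325": ("GltB", 6),
    "SO_2619": ("MetG", 6),
    "SO_3292": ("GuaA", 6),
    "SO_3430": ("RecA", 6),
    "SO_3471": ("GlyA", 6),
    "SO_0009": ("DnaN", 5),
    "SO_1126": ("DnaK", 5),
    "SO_1926": ("GltA", 5),
    "SO_3209": ("CheY", 5),
    "SO_4747": ("AtpD", 5),
    "SO_0610": ("PetC", 4),
    "SO_3432": ("RpoS", 4),
    "SO_3440": ("Eno", 4),
    "SO_4215": ("FtsZ", 4),
    "SO_4586": ("FtsY", 4),
    "SO_4749": ("AtpA", 4),
    "SO_1197": ("FtsH", 3),
}

#: Motif ids -> display names in the published taxonomy.
MOTIF_NAMES: dict[int, str] = {
    1: "Co-regulated PPI",
    2: "Protein Clique",
    3: "Co-regulated Proteins",
    4: "PPI Regulating",
    5: "Bi-feedforward Loop",
    6: "Regulatory Cascade with a Feedback",
    7: "Regulated PPI",
    8: "Feedback with a PPI",
    9: "Bi-regulated Protein",
    10: "Regulatory Cascade",
}

#: Number of thresholded networks (of 6) in which each motif was significant.
MOTIF_TIMES_SIGNIFICANT: dict[int, int] = {
    1: 6, 2: 6, 3: 6, 4: 6, 5: 6, 6: 6, 7: 1, 8: 5, 9: 1, 10: 1,
}

#: Motifs called active across the thresholded networks (ids 7, 9, 10
#: appeared in only one network each and are not active).
ACTIVE_MOTIF_IDS = {1, 2, 3, 4, 5, 6, 8}

#: Motifs conserved across the genus in the companion comparative analysis.
CONSERVED_MOTIF_IDS = {1, 2, 3, 4}

#: Exclusive active motifs = active minus conserved.
EXCLUSIVE_MOTIF_IDS = {5, 6, 8}
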