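"""The published adaptable-database-design (ADD) cluster layout.

The final curated reference design for automated FTIR-imaging microplastics
analysis comprises 32 numbered clusters. The layout below records, for each
cluster, its image-analysis cluster number, its name, and the number of
reference spectra assigned to it. The curation history that produced this
layout was expert work; it is carried here as data, not recomputed.
"""

from __future__ import annotations

__all__ = ["ADD_CLUSTER_TABLE", "ADD_N_CLUSTERS"]

#: (cluster_number, cluster_name, number of contained spectra)
ADD_CLUSTER_TABLE: list[tuple[int, str, int]] = [
    (1, "Polyethylene", 30),
    (2, "Polyethylene oxidized", 2),
    (3, "Polyethylene-chlorinated", 3),
    (4, "Polypropylene", 15),
    (5, "Polystyrene", 11),
    (6, "Polycarbonate", 7),
    (7, "Polyamide", 23),
    (8, "Polyvinylchloride", 6),
    (9, "Cellulose chemical modified", 8),
    (10, "Nitrile rubber", 2),
    (11, "Polyester", 31),
    (12, "Acrylates/polyurethanes/varnish", 27),
    (13, "Animal fur", 27),
    (14, "Plant fibers", 33),
    (15, "Sand", 2),
    (16, "Polysulfone", 4),
    (17, "Polyetheretherketone", 2),
    (18, "Polychloroprene", 2),
    (19, "Chitin", 3),
    (20, "Polyisoprene chlorinated", 1),
    (21, "Polylactic acid", 4),
    (22, "Polycaprolactone", 3),
    (23, "Ethylene-vinyl-acetate", 3),
    (24, "Polyimide", 2),
    (25, "Polyoxymethylene", 3),
    (26, "Polybutadiene", 1),
    (27, "Acrylonitrile-butadiene", 2),
    (28, "Rubber type 1", 3),
    (29, "Rubber type 2", 1),
    (30, "Charcoal", 2),
    (31, "Coal", 4),
    (32, "Rubber type 3", 3),
]

ADD_N_CLUSTERS = len(ADD_CLUSTER_TABLE)
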