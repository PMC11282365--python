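"""Synthetic data generation.

Two kinds of fixtures are produced here:

* the bundled six-species passerine example -- nine source chronograms from
  six studies, a tiny taxonomy carrying the *Emberiza elegans* ->
  *Schoeniclus elegans* synonym, and the target topology whose internal
  nodes are named n1..n5 -- reconstructed exactly from the published
  per-node ages, so the whole pipeline can be exercised end to end with
  known expected output; and
* reproducible random chronogram databases (pure-birth topologies, scaled
  to random root ages) for property and stress tests.

All study citations and the finch-like taxonomy below are synthetic
stand-ins: the names are plausible but the objects are generated, not
copies of any real database.
"""

from __future__ import annotations

import random
from typing import Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .chronodb import ChronogramDB, ChronogramRecord
from .names import ResolvedQuery, TaxonRecord, Taxonomy, make_query
from .trees import (
    Chronogram,
    Tree,
    as_chronogram,
    chronogram_from_node_ages,
    parse_newick,
)

__all__ = [
    "chronogram_from_node_ages",
    "small_example_db",
    "small_example_query_string",
    "random_db",
    "random_chronogram",
    "noisy_studies_db",
    "finchlike_taxonomy",
]

# -- the six-species example ------------------------------------------------

_SPECIES = {
    "PT": "Pheucticus tibialis",
    "RC": "Rhodothraupis celaeno",
    "EC": "Emberiza citrinella",
    "EL": "Emberiza leucocephalos",
    "EE": "Emberiza elegans",  # raw study-tip name; canonical: Schoeniclus elegans
    "SE": "Schoeniclus elegans",
    "PC": "Platyspiza crassirostris",
}

#: the chosen target topology; the cardinal+tanager clade is written first so
#: that root-down preorder names the nodes n1..n5 with n2 = cardinals+tanager,
#: n3 = cardinals, n4 = buntings, n5 = the Emberiza cherry
SMALL_EXAMPLE_TOPOLOGY = (
    "(((Pheucticus_tibialis,Rhodothraupis_celaeno),Platyspiza_crassirostris),"
    "((Emberiza_citrinella,Emberiza_leucocephalos),Schoeniclus_elegans));"
)

#: per-record (citation, topology-newick with raw tip names, clade -> age Myr)
_SMALL_EXAMPLE_RECORDS: list[tuple[str, str, str, dict[frozenset, float]]] = [
    (
        "hooper2017_1",
        "Hooper & Price 2017 - chronogram 1",
        "((Rhodothraupis_celaeno,Platyspiza_crassirostris),"
        "((Emberiza_citrinella,Emberiza_leucocephalos),Emberiza_elegans));",
        {
            frozenset({"RC", "PC", "EC", "EL", "EE"}): 9.651,
            frozenset({"RC", "PC"}): 7.969,
            frozenset({"EC", "EL", "EE"}): 5.324,
            frozenset({"EC", "EL"}): 0.141,
        },
    ),
    (
        "hooper2017_2",
        "Hooper & Price 2017 - chronogram 2",
        "((Rhodothraupis_celaeno,Platyspiza_crassirostris),"
        "((Emberiza_citrinella,Emberiza_leucocephalos),Emberiza_elegans));",
        {
            frozenset({"RC", "PC", "EC", "EL", "EE"}): 21.514,
            frozenset({"RC", "PC"}): 19.709,
            frozenset({"EC", "EL", "EE"}): 10.339,
            frozenset({"EC", "EL"}): 0.273,
        },
    ),
    (
        "barker2015_1",
        "Barker et al. 2015 - chronogram 1",
        "((Pheucticus_tibialis,Rhodothraupis_celaeno),"
        "((Emberiza_citrinella,Emberiza_leucocephalos),Emberiza_elegans));",
        {
            frozenset({"PT", "RC", "EC", "EL", "EE"}): 14.334,
            frozenset({"PT", "RC"}): 10.530,
            frozenset({"EC", "EL", "EE"}): 9.862,
            frozenset({"EC", "EL"}): 0.201,
        },
    ),
    (
        "barker2015_2",
        "Barker et al. 2015 - chronogram 2",
        "((Pheucticus_tibialis,Rhodothraupis_celaeno),"
        "((Emberiza_citrinella,Emberiza_leucocephalos),Emberiza_elegans));",
        {
            frozenset({"PT", "RC", "EC", "EL", "EE"}): 16.298,
            frozenset({"PT", "RC"}): 11.210,
            frozenset({"EC", "EL", "EE"}): 11.732,
            frozenset({"EC", "EL"}): 0.241,
        },
    ),
    (
        "jetz2012_1",
        "Jetz et al. 2012 - chronogram 1",
        "(((Pheucticus_tibialis,Rhodothraupis_celaeno),Platyspiza_crassirostris),"
        "(Emberiza_citrinella,Emberiza_leucocephalos));",
        {
            frozenset({"PT", "RC", "PC", "EC", "EL"}): 22.376,
            frozenset({"PT", "RC", "PC"}): 19.713,
            frozenset({"PT", "RC"}): 18.157,
            frozenset({"EC", "EL"}): 0.576,
        },
    ),
    (
        "jetz2012_2",
        "Jetz et al. 2012 - chronogram 2",
        "((Rhodothraupis_celaeno,Platyspiza_crassirostris),"
        "(Emberiza_citrinella,Emberiza_leucocephalos));",
        {
            frozenset({"RC", "PC", "EC", "EL"}): 22.000,
            frozenset({"RC", "PC"}): 19.709,
            frozenset({"EC", "EL"}): 0.152,
        },
    ),
    (
        "price2014",
        "Price et al. 2014",
        "(((Emberiza_citrinella,Emberiza_leucocephalos),Emberiza_elegans),"
        "Platyspiza_crassirostris);",
        {
            frozenset({"EC", "EL", "EE", "PC"}): 16.950,
            frozenset({"EC", "EL", "EE"}): 12.513,
            frozenset({"EC", "EL"}): 2.290,
        },
    ),
    (
        "claramunt2015",
        "Claramunt & Cracraft 2015",
        "(Pheucticus_tibialis,Platyspiza_crassirostris);",
        {frozenset({"PT", "PC"}): 44.296},
    ),
    (
        "burns2014",
        "Burns et al. 2014",
        "(Pheucticus_tibialis,Rhodothraupis_celaeno);",
        {frozenset({"PT", "RC"}): 10.538},
    ),
]

small_example_query_string = (
    "Pheucticus tibialis, Rhodothraupis celaeno, Emberiza citrinella, "
    "Emberiza leucocephalos, Emberiza elegans, Platyspiza crassirostris"
)


def small_example_taxonomy() -> Taxonomy:
    records = [
        TaxonRecord(1, "Passeriformes", "order", None),
        TaxonRecord(10, "Emberiza", "genus", 1),
        TaxonRecord(11, "Schoeniclus", "genus", 1),
        TaxonRecord(12, "Pheucticus", "genus", 1),
        TaxonRecord(13, "Rhodothraupis", "genus", 1),
        TaxonRecord(14, "Platyspiza", "genus", 1),
        TaxonRecord(100, "Emberiza citrinella", "species", 10),
        TaxonRecord(101, "Emberiza leucocephalos", "species", 10),
        TaxonRecord(102, "Schoeniclus elegans", "species", 11, ("Emberiza elegans",)),
        TaxonRecord(103, "Pheucticus tibialis", "species", 12),
        TaxonRecord(104, "Rhodothraupis celaeno", "species", 13),
        TaxonRecord(105, "Platyspiza crassirostris", "species", 14),
    ]
    return Taxonomy(records, version="small-example-1.0")


def small_example_db() -> tuple[ChronogramDB, Taxonomy, ResolvedQuery, Tree]:
    """The bundled six-species example: database (raw, un-canonicalized tip
    names as published), taxonomy, resolved query, and target topology."""
    taxonomy = small_example_taxonomy()
    records = []
    for record_id, citation, newick, ages in _SMALL_EXAMPLE_RECORDS:
        topology = parse_newick(newick)
        keyed = {
            frozenset(_SPECIES[code] for code in clade): age
            for clade, age in ages.items()
        }
        chrono = chronogram_from_node_ages(topology, keyed)
        records.append(ChronogramRecord(record_id, citation, chrono))
    db = ChronogramDB(records, version="small-example-1.0",
                      taxonomy_version=taxonomy.version)
    query = make_query(small_example_query_string, taxonomy)
    target = parse_newick(SMALL_EXAMPLE_TOPOLOGY)
    return db, taxonomy, query, target


# -- random databases -------------------------------------------------------


def random_chronogram(
    tip_labels: Sequence[str],
    seed: int,
    root_age_range: tuple[float, float] = (5.0, 50.0),
) -> Chronogram:
    """A pure-birth ultrametric tree over ``tip_labels``, rescaled to a root
    age drawn uniformly from ``root_age_range`` (Myr)."""
    if len(tip_labels) < 2:
        raise ValueError("need at least 2 tips")
    rng = random.Random(seed)
    dtree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=len(tip_labels),
        rng=rng,
    )
    # the simulation stops exactly at the last birth, leaving a zero-age
    # cherry; extend every tip branch by the same waiting time so sampling
    # happens strictly after the last speciation (tree stays ultrametric)
    extra = rng.expovariate(len(tip_labels))
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    shuffled = list(tip_labels)
    rng.shuffle(shuffled)
    ns = dendropy.TaxonNamespace()
    for leaf, label in zip(dtree.leaf_node_iter(), shuffled):
        leaf.taxon = dendropy.Taxon(label=label)
        ns.add_taxon(leaf.taxon)
    dtree.taxon_namespace = ns
    chrono = as_chronogram(Tree(dtree))
    target_root = rng.uniform(*root_age_range)
    scale = target_root / chrono.root_age
    clone = chrono.dendropy_tree.clone(depth=1)
    for node in clone.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length *= scale
    return Chronogram(clone)


def random_db(
    n_studies: int,
    tips_per_study: int,
    taxon_pool: Sequence[str],
    seed: int,
    root_age_range: tuple[float, float] = (5.0, 50.0),
) -> ChronogramDB:
    """A reproducible database of independent pure-birth chronograms, each on
    a random subset of the taxon pool."""
    if tips_per_study > len(taxon_pool):
        raise ValueError("taxon pool smaller than tips_per_study")
    if n_studies < 0 or tips_per_study < 2:
        raise ValueError("sizes must be positive (>=2 tips per study)")
    rng = random.Random(seed)
    records = []
    for k in range(n_studies):
        tips = rng.sample(list(taxon_pool), tips_per_study)
        chrono = random_chronogram(tips, seed=rng.randrange(2**31), root_age_range=root_age_range)
        records.append(
            ChronogramRecord(f"study{k:03d}", f"Synthetic study {k:03d}", chrono)
        )
    return ChronogramDB(records, version=f"random-seed{seed}")


def noisy_studies_db(
    n_tips: int,
    n_studies: int,
    noise: float,
    seed: int,
    root_age_range: tuple[float, float] = (10.0, 30.0),
) -> tuple[ChronogramDB, Chronogram]:
    """Several studies re-estimating one true chronogram with centered
    multiplicative age noise (relative scale ``noise``); node-order
    violations introduced by the noise are clamped away, so each record is a
    valid chronogram on the shared topology.  Returns (db, true chronogram).
    """
    pool = [f"Taxon sp{i:03d}" for i in range(n_tips)]
    truth = random_chronogram(pool, seed=seed, root_age_range=root_age_range)
    rng = np.random.default_rng(seed)
    records = []
    topo = Tree(truth.dendropy_tree.clone(depth=1))
    true_ages = {
        truth.tip_set(n): truth.age_of(n) for n in truth.internal_nodes()
    }
    for k in range(n_studies):
        jittered: dict[frozenset, float] = {}
        for node in topo.internal_nodes():  # preorder: parents first
            clade = topo.tip_set(node)
            age = true_ages[clade] * float(rng.uniform(1 - noise, 1 + noise))
            parent = node.parent_node
            if parent is not None:
                cap = jittered[topo.tip_set(parent)]
                age = min(age, 0.999 * cap)
            jittered[clade] = age
        chrono = chronogram_from_node_ages(topo, jittered)
        records.append(
            ChronogramRecord(f"noisy{k:03d}", f"Synthetic noisy study {k:03d}", chrono)
        )
    return ChronogramDB(records, version=f"noisy-seed{seed}"), truth


# -- a finch-like taxonomy at the published scale ---------------------------


def finchlike_taxonomy(n_species: int = 289, n_genera: int = 21) -> Taxonomy:
    """A synthetic family-level taxonomy emulating a finch family with
    ``n_species`` species spread over ``n_genera`` genera, plus a handful of
    subspecific variants (excluded from species expansion) and an outgroup.
    All names are generated; this is a stand-in at the scale of a real
    family, not a copy of any reference taxonomy."""
    records = [
        TaxonRecord(1, "Aves", "class", None),
        TaxonRecord(2, "Passeriformes", "order", 1),
        TaxonRecord(3, "Fringillidae", "family", 2),
        TaxonRecord(4, "Corvidae", "family", 2),
        TaxonRecord(5, "Corvus synthetica", "species", 4),
    ]
    next_id = 10
    genus_ids = []
    for g in range(n_genera):
        records.append(TaxonRecord(next_id, f"Fringillagenus{g:02d}", "genus", 3))
        genus_ids.append(next_id)
        next_id += 1
    for s in range(n_species):
        genus = genus_ids[s % n_genera]
        genus_name = f"Fringillagenus{s % n_genera:02d}"
        sp_id = next_id
        records.append(
            TaxonRecord(sp_id, f"{genus_name} species{s:03d}", "species", genus)
        )
        next_id += 1
        if s % 97 == 0:  # sprinkle a few subspecific variants
            records.append(
                TaxonRecord(
                    next_id,
                    f"{genus_name} species{s:03d} variant",
                    "subspecies",
                    sp_id,
                )
            )
            next_id += 1
    return Taxonomy(records, version="finchlike-synthetic-1.0")
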