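"""Synthetic stand-in tables emulating the mammalian visual-acuity study.

Everything in this module is a constructed emulation, not measured data:
species panels, acuity values and gene status patterns are laid out to
mirror the *published narrative structure* of the low-visual-acuity
gene-loss screen — ten poor-vision species in seven lineages among 49
placental mammals; a focal serpin gene lost in the four subterranean
lineages and one echolocating bat clade; and an extended ~447-assembly
panel in which that gene is inactivated in 70 species falling into 18
independent loss lineages.  Use it to exercise the screen's machinery on
realistically shaped inputs; do not mistake it for the study's actual
supplementary tables.
"""

from __future__ import annotations

import io as _io

import dendropy
import pandas as pd

from .phenotype import AcuityTable

__all__ = [
    "acuity_49",
    "tree_49",
    "serpin_intactness_49",
    "extended_panel",
    "LOW_ACUITY_10",
    "SERPIN_LOST_7",
    "CONTROL_SISTERS",
]

#: the ten poor-vision species (visual acuity < 1 cycles/degree)
LOW_ACUITY_10 = (
    "cape_golden_mole",
    "naked_mole_rat",
    "star_nosed_mole",
    "blind_mole_rat",
    "big_brown_bat",
    "little_brown_bat",
    "davids_myotis_bat",
    "mouse",
    "prairie_vole",
    "deer_mouse",
)

#: species in which the focal serpin gene is scored lost in the 49-panel
SERPIN_LOST_7 = (
    "cape_golden_mole",
    "naked_mole_rat",
    "star_nosed_mole",
    "blind_mole_rat",
    "big_brown_bat",
    "little_brown_bat",
    "davids_myotis_bat",
)

#: higher-acuity sister species of the poor-vision lineages (control
#: foreground for the specificity screen)
CONTROL_SISTERS = (
    "elephant",
    "rhinoceros",
    "horse",
    "flying_fox",
    "black_flying_fox",
    "guinea_pig",
    "degu",
    "squirrel",
)

# species -> (visual acuity in cycles/degree, measurement source); the
# three functionally blind subterranean species carry the assumed-zero
# flag instead of a measurement.  Values are synthetic but ordered like
# the real panel: echolocating bats and murid/cricetid rodents below 1,
# manatee and flying foxes between 1 and 1.5, diurnal ungulates and
# primates high.
_ACUITY = {
    "cape_golden_mole": (0.0, "assumed_zero"),
    "star_nosed_mole": (0.0, "assumed_zero"),
    "blind_mole_rat": (0.0, "assumed_zero"),
    "naked_mole_rat": (0.29, "behavioral"),
    "big_brown_bat": (0.45, "behavioral"),
    "little_brown_bat": (0.5, "behavioral"),
    "davids_myotis_bat": (0.55, "proxy_relative"),
    "mouse": (0.52, "behavioral"),
    "prairie_vole": (0.6, "behavioral"),
    "deer_mouse": (0.9, "behavioral"),
    # between the two screen thresholds (1 and 1.5)
    "rat": (1.1, "behavioral"),
    "manatee": (1.3, "behavioral"),
    "flying_fox": (1.4, "anatomical"),
    "black_flying_fox": (1.45, "anatomical"),
    # background
    "shrew": (1.7, "anatomical"),
    "hedgehog": (1.9, "anatomical"),
    "tenrec": (2.0, "anatomical"),
    "guinea_pig": (2.7, "behavioral"),
    "degu": (2.9, "anatomical"),
    "rabbit": (3.0, "behavioral"),
    "pika": (3.1, "proxy_relative"),
    "squirrel": (3.9, "behavioral"),
    "kangaroo_rat": (4.0, "proxy_relative"),
    "tree_shrew": (4.4, "behavioral"),
    "armadillo": (4.8, "anatomical"),
    "aardvark": (5.0, "anatomical"),
    "opossum_relative": (5.2, "proxy_relative"),
    "pig": (5.5, "anatomical"),
    "alpaca": (6.0, "proxy_relative"),
    "cat": (6.3, "behavioral"),
    "dog": (7.0, "behavioral"),
    "ferret": (7.5, "anatomical"),
    "panda": (8.0, "anatomical"),
    "dolphin": (8.2, "behavioral"),
    "killer_whale": (8.5, "proxy_relative"),
    "sloth": (10.2, "behavioral"),
    "goat": (11.0, "anatomical"),
    "sheep": (11.5, "anatomical"),
    "elephant": (13.16, "behavioral"),
    "horse": (16.5, "behavioral"),
    "rhinoceros": (17.0, "proxy_relative"),
    "cow": (18.0, "anatomical"),
    "marmoset": (30.0, "behavioral"),
    "macaque": (44.0, "behavioral"),
    "baboon": (45.0, "proxy_relative"),
    "gorilla": (50.0, "proxy_relative"),
    "orangutan": (52.0, "proxy_relative"),
    "chimp": (55.0, "behavioral"),
    "human": (60.0, "behavioral"),
}

# 49-species topology (branch lengths ~millions of years).  The
# poor-vision species fall into seven maximal all-foreground clades: four
# subterranean singletons, the echolocating bat clade, mouse (the
# high-acuity rat splits Muridae from Cricetidae) and the vole +
# deer-mouse clade.
_TREE_49 = """(
 (
  ((cape_golden_mole:70,tenrec:70):10,aardvark:80):10,
  (elephant:60,manatee:60):30
 ):15,
 (
  (armadillo:70,sloth:70):30,
  (
   (
    (
     ((mouse:12,rat:12):14,(prairie_vole:10,deer_mouse:10):16):9,
     blind_mole_rat:35
    ):25,
    ((guinea_pig:30,degu:30):25,naked_mole_rat:55):5,
    squirrel:58,
    kangaroo_rat:58
   ):22,
   (rabbit:50,pika:50):30,
   (tree_shrew:72,
    ((marmoset:18,(macaque:10,baboon:10):8):10,
     ((gorilla:9,(chimp:7,human:7):2):4,orangutan:13):15
    ):44
   ):8,
   (
    (
     ((big_brown_bat:25,(little_brown_bat:15,davids_myotis_bat:15):10):30,
      (flying_fox:22,black_flying_fox:22):33
     ):18,
     (
      (horse:55,rhinoceros:55):12,
      ((cat:40,(dog:35,(ferret:30,panda:30):5):5):20,
       ((pig:50,alpaca:50):8,((cow:25,(goat:12,sheep:12):13):20,
        (dolphin:20,killer_whale:20):25):13):2
      ):7
     ):6
    ):8,
    ((star_nosed_mole:55,shrew:55):10,hedgehog:65):16
   ):4,
   opossum_relative:85
  ):15
 ):5
):0;
"""


def tree_49() -> dendropy.Tree:
    """The 49-species tree of the screen panel (synthetic stand-in)."""
    tree = dendropy.Tree.get(
        data=_TREE_49, schema="newick", preserve_underscores=True
    )
    return tree


def acuity_49() -> AcuityTable:
    """Visual-acuity table for the 49-species panel (synthetic stand-in)."""
    rows = [
        {"species_id": sp, "va": va, "source": src}
        for sp, (va, src) in sorted(_ACUITY.items())
    ]
    return AcuityTable(pd.DataFrame(rows))


def serpin_intactness_49() -> pd.Series:
    """%intact of the focal serpin gene across the 49 species.

    Lost (<60) in the four subterranean species and the three
    echolocating bats; intact elsewhere.  Synthetic values shaped to the
    published loss pattern.
    """
    vals = {sp: 100.0 for sp in _ACUITY}
    lost_levels = [0.0, 12.0, 25.0, 31.0, 42.0, 48.0, 55.0]
    for sp, v in zip(SERPIN_LOST_7, lost_levels):
        vals[sp] = v
    return pd.Series(vals, name="serpin")


# ------------------------------------------------ extended 447-assembly panel

# 18 independent loss lineages of the focal gene across placental
# mammals, as (clade name, lost species count, intact sister count).
# Eighteen lineages, 70 inactivated species in total; intact sisters keep
# the lineages separated on the tree.
_LOSS_LINEAGES = [
    ("afroinsectiphilia", 9, 2),  # aardvark, elephant shrew, golden moles, tenrecs
    ("sirenia", 2, 2),  # dugong + manatee; elephants intact
    ("cingulata", 7, 2),  # armadillos
    ("pilosa", 6, 2),  # sloths + anteaters
    ("manidae", 6, 2),  # pangolins
    ("solenodon", 1, 2),
    ("european_shrew", 1, 3),
    ("talpidae", 6, 3),  # fossorial moles incl. star-nosed
    ("naked_mole_rat", 1, 4),
    ("blind_mole_rat", 1, 4),
    ("damara_mole_rat", 1, 4),
    ("myotis_bats", 6, 2),
    ("vesper_bats", 5, 2),
    ("big_brown_bats", 2, 2),
    ("horseshoe_bats", 5, 2),
    ("roundleaf_bats", 5, 2),
    ("trident_bats", 2, 2),
    ("funnel_eared_bats", 4, 2),
]

_N_EXTRA_INTACT = 333  # additional background species (447 assemblies total)
_N_MISSING = 17  # assemblies too incomplete to score


def extended_panel() -> tuple[dendropy.Tree, dict[str, str]]:
    """The ~447-assembly panel: tree plus per-species gene status.

    Returns a tree over 447 species and a status map with 70 ``lost``
    species in 18 independent lineages, ``missing`` entries scattered in
    the background, and everything else ``intact`` (synthetic stand-in
    shaped to the published counts).
    """
    parts = []
    statuses: dict[str, str] = {}
    depth = 80.0
    for clade, n_lost, n_intact in _LOSS_LINEAGES:
        lost = [f"{clade}_lost{i}" for i in range(1, n_lost + 1)]
        sisters = [f"{clade}_sister{i}" for i in range(1, n_intact + 1)]
        for s in lost:
            statuses[s] = "lost"
        for s in sisters:
            statuses[s] = "intact"
        lost_sub = _ladder(lost, 10.0)
        sister_sub = _ladder(sisters, 10.0)
        parts.append(f"({lost_sub}:30,{sister_sub}:30)")
    extra = [f"background_{i}" for i in range(1, _N_EXTRA_INTACT + 1)]
    for i, s in enumerate(extra):
        statuses[s] = "missing" if i < _N_MISSING else "intact"
    parts.append(_ladder(extra, 5.0) + ":30")
    newick = "(" + ",".join(f"{p}:{depth}" for p in parts[:-1])
    newick += "," + parts[-1] + "):0;"
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return tree, statuses


def _ladder(names: list[str], step: float) -> str:
    """Pectinate subtree over the given leaves."""
    if len(names) == 1:
        return f"{names[0]}:{step}"
    inner = f"({names[0]}:{step},{names[1]}:{step})"
    h = step
    for name in names[2:]:
        h += step
        inner = f"({inner}:{step},{name}:{h})"
    return inner
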