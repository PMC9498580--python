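"""Packaged study fixtures: the annotated variant tables, cohort, panels,
and a synthetic interaction network.

The four variant tables transcribe the study's printed candidate-gene
tables (TGA-associated, motile cilia, non-motile cilia, ciliogenesis/
trafficking; 14, 31, 13 and 19 rows).  The same variant can legitimately
appear in more than one table — panels overlap — so cohort-level
computations should deduplicate with :func:`unique_patient_variants`.

The interaction network is a *synthetic* stand-in for the external STRING
database (see ``data/synthetic_string_edges.tsv``); the study's global
network-level counts are therefore not reproducible from it and are not
attempted.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Dict, List

import networkx as nx

from .io import read_edge_list, read_panel, read_variant_table
from .models import Cohort, GenePanel, VariantRecord

TABLE_FILES = {
    "tga_associated": "table1_tga_associated.tsv",
    "motile": "table2_motile.tsv",
    "non_motile": "table3_non_motile.tsv",
    "ciliogenesis_trafficking": "table4_ciliogenesis_trafficking.tsv",
}

PANEL_FILES = {
    "tga_associated": "panel_tga_associated.txt",
    "motile": "panel_motile.txt",
    "non_motile": "panel_non_motile.txt",
    "ciliogenesis_trafficking": "panel_ciliogenesis_trafficking.txt",
}


def _data_path(filename: str):
    return resources.files("ciliavar.data").joinpath(filename)


def load_table(name: str) -> List[VariantRecord]:
    """Load one of the four study variant tables by panel name."""
    with resources.as_file(_data_path(TABLE_FILES[name])) as path:
        return read_variant_table(path)


def load_study_variants() -> List[VariantRecord]:
    """All study variant observations, in table order (duplicates included)."""
    records: List[VariantRecord] = []
    for name in TABLE_FILES:
        records.extend(load_table(name))
    return records


def load_study_cohort() -> Cohort:
    """The 11-proband study cohort (9 males, 2 females)."""
    with resources.as_file(_data_path("cohort.tsv")) as path:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            patients = tuple(
                (row["patient_id"].strip(), row["sex"].strip()) for row in reader
            )
    return Cohort(patients=patients)


def load_panels() -> Dict[str, GenePanel]:
    """The four candidate-gene panels, keyed by panel name."""
    panels = {}
    for name, filename in PANEL_FILES.items():
        with resources.as_file(_data_path(filename)) as path:
            panels[name] = read_panel(path, name=name)
    return panels


def load_interaction_graph() -> nx.Graph:
    """The synthetic STRING-dialect interaction network."""
    with resources.as_file(_data_path("synthetic_string_edges.tsv")) as path:
        return read_edge_list(path, score_scale="string_999")


def unique_patient_variants(records) -> List[VariantRecord]:
    """Deduplicate observations by (patient, gene, cDNA change), keeping the
    first occurrence.  Needed because panels overlap across tables."""
    seen = set()
    out = []
    for r in records:
        key = (r.patient_id, r.gene, r.nt_change)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out
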