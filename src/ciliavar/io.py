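"""Readers and writers for annotated variant tables, gene panels, edge lists.

The variant table is a UTF-8 TSV, one row per patient x variant, with the
columns of :class:`~ciliavar.models.VariantRecord` flattened (the predictor
profile contributes eleven columns).  Two dialect quirks inherited from the
printed source tables are handled here:

* scientific notation may be written ``3.95e-4`` or ``3.95 x 10^-4`` (with
  ``x`` or ``×``, ASCII or Unicode minus);
* a trailing asterisk on the frequency cell marks a *global* reference
  frequency (used where no Latino/Admixed-American stratum frequency is
  available); ``New`` marks a novel variant with no frequency at all, and
  ``NF`` a known variant whose frequency the reference does not report.

Gene panels are plain text, one symbol per line, ``#`` comments allowed.
Edge lists are (node, node, score) triples, either unit-scale confidences
or STRING protein-links exports with integer combined scores on 0-999.
"""

from __future__ import annotations

import csv
import math
import re
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import networkx as nx

from .errors import FormatError, ValidationError
from .models import (
    NOVEL_MARKER,
    Cohort,
    GenePanel,
    PredictorProfile,
    VariantRecord,
    new_interaction_graph,
)

_MANDATORY_COLUMNS = [
    "patient_id",
    "gene",
    "dbsnp",
    "nt_change",
    "consequence",
    "aa_change",
    "sift_label",
    "sift_score",
    "pp2_humdiv_label",
    "pp2_humdiv_score",
    "pp2_humvar_label",
    "pp2_humvar_score",
    "ma_label",
    "ma_score",
    "cadd_phred",
    "loftool_label",
    "loftool_score",
    "allele_freq",
    "zygosity",
    "chromosome_class",
    "inheritance",
    "panel",
    "clinical_class",
]

_CONSEQUENCE_ALIASES = {
    "M": "missense",
    "N": "nonsense",
    "F": "frameshift",
    "S": "splice",
    "I": "inframe_indel",
    "missense": "missense",
    "nonsense": "nonsense",
    "frameshift": "frameshift",
    "splice": "splice",
    "inframe_indel": "inframe_indel",
}

_ZYGOSITY_ALIASES = {
    "HE": "het",
    "HETO": "het",
    "HO": "hom",
    "HOMO": "hom",
    "HEMY": "hemi",
    "het": "het",
    "hom": "hom",
    "hemi": "hemi",
}

_SCI_RE = re.compile(
    r"^\s*([0-9]*\.?[0-9]+)\s*[x×]\s*10\s*\^?\s*([+-]?[0-9]+)\s*$"
)


def parse_number(cell: str) -> Optional[float]:
    """Parse a decimal cell accepting both ``e`` and ``x 10^`` notations.

    Empty cells return ``None``.  Raises :class:`ValueError` on malformed
    input (callers attach the row number).
    """
    text = cell.strip()
    if not text:
        return None
    # normalize Unicode minus and superscript markers from extracted tables
    text = text.replace("−", "-").replace("^", "^").strip()
    m = _SCI_RE.match(text)
    if m:
        return float(m.group(1)) * 10.0 ** int(m.group(2))
    return float(text)


def parse_frequency(cell: str):
    """Parse an allele-frequency cell of the source dialect.

    Returns ``(value, scope, not_found)`` where *value* is ``None`` for the
    novelty marker ``New`` and for the explicit not-found marker ``NF``, and
    *scope* is ``"global"`` iff the cell carried a trailing asterisk.
    """
    text = cell.strip()
    scope = "latino"
    if text.endswith("*"):
        scope = "global"
        text = text[:-1].strip()
    if text == NOVEL_MARKER:
        return None, scope, False
    if text in {"NF", ""}:
        return None, scope, text == "NF"
    return parse_number(text), scope, False


def _field(row: dict, name: str) -> str:
    return (row.get(name) or "").strip()


def read_variant_table(path) -> List[VariantRecord]:
    """Read an annotated variant table into :class:`VariantRecord` objects.

    Raises :class:`FormatError` for missing mandatory columns or malformed
    numeric cells (all offending rows reported at once, with line numbers),
    and :class:`ValidationError` for vocabulary violations, naming the row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames
        if header is None:
            raise FormatError(f"{path}: empty file, header row required")
        missing = [c for c in _MANDATORY_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")
        extra_cols = [c for c in header if c not in _MANDATORY_COLUMNS]

        records: List[VariantRecord] = []
        bad_numeric: List[str] = []
        for lineno, row in enumerate(reader, start=2):
            cq_raw = _field(row, "consequence")
            consequence = _CONSEQUENCE_ALIASES.get(cq_raw)
            if consequence is None:
                raise ValidationError(
                    f"{path} row {lineno}: consequence {cq_raw!r} outside vocabulary"
                )
            zyg_raw = _field(row, "zygosity")
            zygosity = _ZYGOSITY_ALIASES.get(zyg_raw)
            if zygosity is None:
                raise ValidationError(
                    f"{path} row {lineno}: zygosity {zyg_raw!r} outside vocabulary"
                )

            def num(name, lineno=lineno, row=row):
                try:
                    return parse_number(_field(row, name))
                except ValueError:
                    bad_numeric.append(
                        f"row {lineno}: column {name!r} = {_field(row, name)!r}"
                    )
                    return None

            try:
                freq, scope, not_found = parse_frequency(_field(row, "allele_freq"))
            except ValueError:
                bad_numeric.append(
                    f"row {lineno}: column 'allele_freq' = "
                    f"{_field(row, 'allele_freq')!r}"
                )
                freq, scope, not_found = None, "latino", True

            profile_kwargs = dict(
                sift_label=_field(row, "sift_label") or None,
                sift_score=num("sift_score"),
                pp2_humdiv_label=_field(row, "pp2_humdiv_label") or None,
                pp2_humdiv_score=num("pp2_humdiv_score"),
                pp2_humvar_label=_field(row, "pp2_humvar_label") or None,
                pp2_humvar_score=num("pp2_humvar_score"),
                ma_label=_field(row, "ma_label") or None,
                ma_score=num("ma_score"),
                cadd_phred=num("cadd_phred"),
                loftool_label=_field(row, "loftool_label") or None,
                loftool_score=num("loftool_score"),
            )
            if bad_numeric:
                continue  # keep scanning to report every malformed cell
            try:
                record = VariantRecord(
                    patient_id=_field(row, "patient_id"),
                    gene=_field(row, "gene"),
                    dbsnp=_field(row, "dbsnp"),
                    nt_change=_field(row, "nt_change"),
                    consequence=consequence,
                    aa_change=_field(row, "aa_change") or None,
                    predictors=PredictorProfile(**profile_kwargs),
                    allele_freq=freq,
                    freq_scope=scope,
                    freq_not_found=not_found,
                    zygosity=zygosity,
                    chromosome_class=_field(row, "chromosome_class") or "autosomal",
                    inheritance=_field(row, "inheritance") or "NR",
                    panel=_field(row, "panel"),
                    clinical_class=_field(row, "clinical_class") or "unclassified",
                    extra={c: _field(row, c) for c in extra_cols if _field(row, c)},
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} row {lineno}: {exc}") from exc
            records.append(record)

        if bad_numeric:
            raise FormatError(
                f"{path}: malformed numeric cell(s): " + "; ".join(bad_numeric)
            )
    return records


def _format_number(value: Optional[float]) -> str:
    if value is None:
        return ""
    if math.isfinite(value) and value == int(value) and abs(value) < 1e15:
        # keep integers readable but unambiguous as floats
        return repr(float(value))
    return repr(value)


def write_variant_table(records: Sequence[VariantRecord], path) -> None:
    """Write records as the canonical TSV dialect (round-trips exactly)."""
    path = Path(path)
    extra_cols = sorted({k for r in records for k in r.extra})
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MANDATORY_COLUMNS + extra_cols)
        for r in records:
            p = r.predictors
            if r.is_novel:
                freq_cell = NOVEL_MARKER
            elif r.allele_freq is None:
                freq_cell = "NF"
            else:
                freq_cell = _format_number(r.allele_freq)
            if r.freq_scope == "global":
                freq_cell += " *"
            writer.writerow(
                [
                    r.patient_id,
                    r.gene,
                    r.dbsnp,
                    r.nt_change,
                    r.consequence,
                    r.aa_change or "",
                    p.sift_label or "",
                    _format_number(p.sift_score),
                    p.pp2_humdiv_label or "",
                    _format_number(p.pp2_humdiv_score),
                    p.pp2_humvar_label or "",
                    _format_number(p.pp2_humvar_score),
                    p.ma_label or "",
                    _format_number(p.ma_score),
                    _format_number(p.cadd_phred),
                    p.loftool_label or "",
                    _format_number(p.loftool_score),
                    freq_cell,
                    r.zygosity,
                    r.chromosome_class,
                    r.inheritance,
                    r.panel,
                    r.clinical_class,
                ]
                + [r.extra.get(c, "") for c in extra_cols]
            )


def read_panel(path, name: Optional[str] = None) -> GenePanel:
    """Read a gene panel: one symbol per line, ``#`` comments, deduplicated."""
    path = Path(path)
    genes = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        symbol = line.split("#", 1)[0].strip()
        if symbol:
            genes.add(symbol)
    if not genes:
        raise ValidationError(f"{path}: panel contains no gene symbols")
    return GenePanel(name=name or path.stem, genes=frozenset(genes))


def read_cohort(path) -> Cohort:
    """Read a cohort TSV with ``patient_id`` and ``sex`` columns."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"patient_id", "sex"} <= set(
            reader.fieldnames
        ):
            raise FormatError(f"{path}: cohort file needs patient_id and sex columns")
        patients = tuple(
            (row["patient_id"].strip(), row["sex"].strip()) for row in reader
        )
    return Cohort(patients=patients)


def write_cohort(cohort: Cohort, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("patient_id\tsex\n")
        for pid, sex in cohort.patients:
            fh.write(f"{pid}\t{sex}\n")


def read_edge_list(path, score_scale: str = "unit") -> nx.Graph:
    """Read a weighted edge list into an interaction graph.

    ``score_scale="string_999"`` divides integer combined scores by 1000
    (the STRING protein-links export convention); ``"unit"`` takes scores
    as confidences directly.  Symmetric duplicates keep the maximum
    confidence; self-edges are dropped (node retained).
    """
    if score_scale not in {"unit", "string_999"}:
        raise ValidationError(f"score_scale={score_scale!r}")
    path = Path(path)
    triples = []
    seen_data = False
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        parts = text.replace("\t", " ").split()
        if len(parts) != 3:
            raise FormatError(f"{path} line {lineno}: expected 'node node score'")
        u, v, raw = parts
        try:
            score = float(raw)
        except ValueError:
            if not seen_data:
                continue  # header line (e.g. STRING's "protein1 protein2 combined_score")
            raise FormatError(f"{path} line {lineno}: malformed score {raw!r}")
        seen_data = True
        if score_scale == "string_999":
            score /= 1000.0
        if not (0.0 <= score <= 1.0):
            raise ValidationError(
                f"{path} line {lineno}: confidence {score} outside [0, 1] after scaling"
            )
        triples.append((u, v, score))
    return new_interaction_graph(triples)


def write_edge_list(graph: nx.Graph, path, score_scale: str = "unit") -> None:
    """Write an interaction graph in the same dialects :func:`read_edge_list` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for u, v in sorted(graph.edges):
            conf = graph.edges[u, v]["confidence"]
            if score_scale == "string_999":
                fh.write(f"{u}\t{v}\t{round(conf * 1000):d}\n")
            else:
                fh.write(f"{u}\t{v}\t{conf!r}\n")
        for node in sorted(n for n in graph.nodes if graph.degree(n) == 0):
            fh.write(f"# isolated node: {node}\n")
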