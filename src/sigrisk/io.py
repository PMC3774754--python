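"""Input handling: expression matrices, clinical tables, gene signatures,
and NCBI ``gene_info``-format annotation, plus the gene-level preprocessing
steps (identifier resolution, probe collapsing, log2 / quantile-normalization).

Conventions
-----------
Expression files are TSV/CSV with probe (or gene) identifiers in the first
column and sample identifiers in the header row.  Clinical tables are
delimited files with named time-to-event and event-indicator columns.
Signatures are one identifier per line with an optional second column of
per-gene weights.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix", "ClinicalTable", "GeneSignature", "GeneRecord",
    "GeneResolution", "AnnotationIndex",
    "read_expression", "read_clinical", "read_signature", "read_gene_info",
    "resolve_signature", "collapse_probes", "preprocess",
    "quantile_normalize", "join_samples",
]

LOG2_AUTO_THRESHOLD = 50.0  # max value above this implies linear-scale data


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probes/genes x samples numeric matrix with optional probe annotation.

    ``values`` rows align with ``probe_ids``, columns with ``sample_ids``.
    After :func:`preprocess` all values are finite log2 expression.
    ``annotation`` maps probe_id -> :class:`GeneRecord` where known.
    """

    probe_ids: list
    sample_ids: list
    values: np.ndarray
    annotation: dict = field(default_factory=dict)
    n_missing: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples")
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {name} ids: {', '.join(map(str, dup))}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.probe_ids), list(sample_ids),
                                self.values[:, idx], dict(self.annotation))

    def row(self, probe_id) -> np.ndarray:
        return self.values[self.probe_ids.index(probe_id)]


@dataclass
class ClinicalTable:
    """Per-sample censored outcome plus optional clinical covariates."""

    sample_ids: list
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame
    time_unit: str = "unspecified"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match sample_ids")
        if np.any(self.time <= 0) or not np.all(np.isfinite(self.time)):
            bad = [self.sample_ids[i] for i in
                   np.flatnonzero(~np.isfinite(self.time) | (self.time <= 0))]
            raise ValueError(f"non-positive or non-numeric time for samples: "
                             f"{', '.join(map(str, bad))}")
        if not np.all(np.isin(self.event, (0, 1))):
            bad = [self.sample_ids[i] for i in
                   np.flatnonzero(~np.isin(self.event, (0, 1)))]
            raise ValueError(f"event indicator outside {{0,1}} for samples: "
                             f"{', '.join(map(str, bad))}")

    def subset(self, sample_ids) -> "ClinicalTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ClinicalTable(list(sample_ids), self.time[idx], self.event[idx],
                             self.covariates.iloc[idx].reset_index(drop=True),
                             self.time_unit)


@dataclass
class GeneSignature:
    """Gene identifiers with optional user-supplied risk weights.

    Weights must be present for all entries or absent for all: a partially
    weighted signature is ambiguous as a prognostic-index definition.
    """

    entries: list  # list of (identifier, weight-or-None)
    id_space: str = "auto"

    def __post_init__(self):
        if not self.entries:
            raise ValueError("signature has no identifiers")
        if any(not str(ident).strip() for ident, _ in self.entries):
            raise ValueError("signature contains an empty identifier")
        weights = [w for _, w in self.entries]
        has = [w is not None for w in weights]
        if any(has) and not all(has):
            raise ValueError("weights must be given for all genes or none")
        if self.id_space not in ("symbol", "entrez", "ensembl", "hgnc", "auto"):
            raise ValueError(f"unknown id space: {self.id_space}")

    @property
    def identifiers(self) -> list:
        return [ident for ident, _ in self.entries]

    @property
    def weights(self):
        ws = [w for _, w in self.entries]
        return None if ws[0] is None else np.asarray(ws, dtype=float)

    @property
    def weighted(self) -> bool:
        return self.entries[0][1] is not None


@dataclass
class GeneRecord:
    entrez: str
    symbol: str
    synonyms: tuple = ()
    ensembl: tuple = ()
    hgnc: tuple = ()


@dataclass
class GeneResolution:
    """Outcome of mapping signature identifiers onto expression rows.

    Every input identifier lands in exactly one of ``matched`` (with its
    probe rows) or ``unmatched``.  ``notes`` records synonym-based or
    otherwise ambiguous matches.
    """

    matched: dict          # identifier -> list of probe_ids
    unmatched: list
    notes: dict = field(default_factory=dict)

    @property
    def n_found(self) -> int:
        return len(self.matched)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _sep(dialect, path):
    if dialect == "auto":
        dialect = "csv" if str(path).endswith(".csv") else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect: {dialect}")
    return "\t" if dialect == "tsv" else ","

_NA_TOKENS = {"", "NA", "N/A", "NAN", "NULL", "NONE", "."}


def read_expression(path, dialect="auto") -> ExpressionMatrix:
    """Read a probes x samples expression file (first column = probe ids)."""
    sep = _sep(dialect, path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False, skip_blank_lines=True)
    if df.index.has_duplicates:
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate probe ids: {', '.join(map(str, dup))}")

    def parse(cell):
        s = str(cell).strip()
        if s.upper() in _NA_TOKENS:
            return np.nan
        try:
            return float(s)
        except ValueError as exc:
            raise ValueError(f"non-numeric expression value {cell!r}") from exc

    values = df.map(parse).to_numpy(dtype=float)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.info("expression file %s: %d missing values", path, n_missing)
    return ExpressionMatrix(list(df.index.astype(str)),
                            list(df.columns.astype(str)),
                            values, n_missing=n_missing)


def read_clinical(path, time_col, event_col, dialect="auto",
                  event_map=None, time_unit="unspecified") -> ClinicalTable:
    """Read a clinical table; coerce time to positive reals, event to {0,1}.

    ``event_map`` optionally maps string codes (e.g. ``DECEASED``/``LIVING``)
    to 1/0.  Remaining columns are kept untouched as covariates.
    """
    sep = _sep(dialect, path)
    df = pd.read_csv(path, sep=sep)
    df.columns = [str(c) for c in df.columns]
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"clinical table missing column {col!r}")
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    time = pd.to_numeric(df[time_col], errors="coerce").to_numpy()
    if np.any(~np.isfinite(time)):
        bad = [sample_ids[i] for i in np.flatnonzero(~np.isfinite(time))]
        raise ValueError(f"non-numeric time for samples: {', '.join(bad)}")

    ev_raw = df[event_col]
    if event_map:
        norm = {str(k).strip().upper(): v for k, v in event_map.items()}
        ev = ev_raw.map(lambda v: norm.get(str(v).strip().upper(), v))
    else:
        ev = ev_raw
    ev = pd.to_numeric(ev, errors="coerce").to_numpy()
    if np.any(~np.isin(ev, (0.0, 1.0))):
        bad = [sample_ids[i] for i in np.flatnonzero(~np.isin(ev, (0.0, 1.0)))]
        raise ValueError(f"event indicator outside {{0,1}} for samples: "
                         f"{', '.join(bad)}")

    cov_cols = [c for c in df.columns[1:] if c not in (time_col, event_col)]
    covariates = df[cov_cols].reset_index(drop=True)
    return ClinicalTable(sample_ids, time, ev.astype(int), covariates, time_unit)


def read_signature(path, id_space="auto") -> GeneSignature:
    """Read a signature file: one identifier per line, optional weight column."""
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            ident = parts[0].strip()
            weight = float(parts[1]) if len(parts) > 1 and parts[1].strip() else None
            entries.append((ident, weight))
    return GeneSignature(entries, id_space=id_space)


# ---------------------------------------------------------------------------
# NCBI gene_info annotation
# ---------------------------------------------------------------------------

class AnnotationIndex:
    """Lookup from gene identifiers of several kinds to canonical records.

    Precedence at query time: exact Entrez id > official symbol >
    Ensembl/HGNC cross-reference > synonym.  Symbol-space lookups are
    case-insensitive; synonym hits are flagged lower-confidence.
    """

    def __init__(self):
        self.by_entrez = {}
        self.by_symbol = {}
        self.by_xref = {}
        self.by_synonym = {}   # upper-cased synonym -> list of records

    def add(self, rec: GeneRecord):
        self.by_entrez[rec.entrez] = rec
        self.by_symbol[rec.symbol.upper()] = rec
        for x in rec.ensembl + rec.hgnc:
            self.by_xref[x.upper()] = rec
        for syn in rec.synonyms:
            self.by_synonym.setdefault(syn.upper(), []).append(rec)

    def __len__(self):
        return len(self.by_entrez)

    def lookup(self, identifier):
        """Return ``(record, how)`` or ``(None, None)``.

        ``how`` is one of ``entrez``/``symbol``/``xref``/``synonym``; a
        synonym that names several genes resolves to the record whose
        official symbol sorts first, noted as ``synonym-ambiguous``.
        """
        ident = str(identifier).strip()
        if ident in self.by_entrez:
            return self.by_entrez[ident], "entrez"
        up = ident.upper()
        if up in self.by_symbol:
            return self.by_symbol[up], "symbol"
        if up in self.by_xref:
            return self.by_xref[up], "xref"
        if up in self.by_synonym:
            recs = self.by_synonym[up]
            if len(recs) == 1:
                return recs[0], "synonym"
            best = min(recs, key=lambda r: r.symbol)
            return best, "synonym-ambiguous"
        return None, None


def read_gene_info(path) -> AnnotationIndex:
    """Parse an NCBI gene_info-format file (plain or gzip) into an index.

    Expected tab-delimited columns include GeneID, Symbol, Synonyms and
    dbXrefs (``HGNC:...|Ensembl:...``).  Malformed lines are skipped with a
    warning; an empty result raises.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    index = AnnotationIndex()
    with opener(path, "rt") as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
        cols = {name: i for i, name in enumerate(header)}
        required = ("GeneID", "Symbol", "Synonyms", "dbXrefs")
        if not all(c in cols for c in required):
            raise ValueError("not a gene_info-format file: missing "
                             + ", ".join(c for c in required if c not in cols))
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(header):
                logger.warning("gene_info line %d malformed; skipped", lineno)
                continue
            entrez = parts[cols["GeneID"]].strip()
            symbol = parts[cols["Symbol"]].strip()
            if not entrez or not symbol:
                logger.warning("gene_info line %d malformed; skipped", lineno)
                continue
            syns = tuple(s for s in parts[cols["Synonyms"]].split("|")
                         if s and s != "-")
            ens, hgnc = [], []
            for xref in parts[cols["dbXrefs"]].split("|"):
                if xref.startswith("Ensembl:"):
                    ens.append(xref.split(":", 1)[1])
                elif xref.startswith("HGNC:"):
                    hgnc.append(xref.split("HGNC:")[-1] if "HGNC:HGNC:" in xref
                                else xref.split(":", 1)[1])
            index.add(GeneRecord(entrez, symbol, syns, tuple(ens), tuple(hgnc)))
    if len(index) == 0:
        raise ValueError("empty annotation index")
    return index


# ---------------------------------------------------------------------------
# Resolution and collapsing
# ---------------------------------------------------------------------------

def resolve_signature(sig: GeneSignature, ann: AnnotationIndex | None,
                      expr: ExpressionMatrix) -> GeneResolution:
    """Map each signature identifier to the probe rows present in ``expr``.

    Works with or without annotation: when ``expr`` rows carry probe
    annotation the match is through canonical gene records; otherwise
    row ids are compared directly against the identifier (and its official
    symbol / Entrez id when an annotation index is supplied).
    """
    # probe lookup tables for the expression matrix
    probes_by_symbol: dict = {}
    probes_by_entrez: dict = {}
    for pid in expr.probe_ids:
        rec = expr.annotation.get(pid)
        if rec is not None:
            probes_by_symbol.setdefault(rec.symbol.upper(), []).append(pid)
            probes_by_entrez.setdefault(rec.entrez, []).append(pid)
    probes_by_rowid = {str(p).upper(): p for p in expr.probe_ids}

    matched, unmatched, notes = {}, [], {}
    for ident in sig.identifiers:
        rec, how = ann.lookup(ident) if ann is not None else (None, None)
        hits: list = []
        if rec is not None:
            hits = probes_by_entrez.get(rec.entrez, []) or \
                probes_by_symbol.get(rec.symbol.upper(), [])
            if not hits:  # expression rows may be gene-level already
                for key in (rec.symbol.upper(), rec.entrez):
                    if key.upper() in probes_by_rowid:
                        hits = [probes_by_rowid[key.upper()]]
                        break
        if not hits:
            direct = probes_by_rowid.get(str(ident).strip().upper())
            if direct is not None:
                hits = [direct]
                how = how or "rowid"
        if hits:
            matched[ident] = sorted(hits)
            if how in ("synonym", "synonym-ambiguous", "xref"):
                label = rec.symbol if rec is not None else ident
                notes[ident] = f"matched via {how} -> {label}"
        else:
            unmatched.append(ident)
    if not matched:
        raise ValueError("empty signature after resolution: no identifier "
                         "matched any expression row")
    if unmatched:
        logger.info("unmatched identifiers: %s", ", ".join(unmatched))
    return GeneResolution(matched, unmatched, notes)


def collapse_probes(expr: ExpressionMatrix, resolution: GeneResolution,
                    method="max_row_average") -> ExpressionMatrix:
    """Collapse multi-probe genes to one row per resolved gene.

    ``max_row_average`` keeps the probe with the largest across-sample mean
    (the retained row is an original probe row, values untouched);
    ``mean`` averages the gene's probes element-wise; ``max_variance`` keeps
    the probe with the largest across-sample variance.  Ties break to the
    lexicographically smallest probe id.
    """
    if method not in ("max_row_average", "mean", "max_variance"):
        raise ValueError(f"unknown collapse method: {method}")
    if not resolution.matched:
        raise ValueError("empty resolution")
    frame = expr.to_frame()
    rows, ids = [], []
    for ident in resolution.matched:  # insertion order = signature order
        probes = resolution.matched[ident]
        sub = frame.loc[probes]
        if method == "mean":
            rows.append(sub.mean(axis=0).to_numpy())
        else:
            crit = sub.mean(axis=1) if method == "max_row_average" else sub.var(axis=1, ddof=1)
            if len(probes) == 1:
                best = probes[0]
            else:
                best_val = crit.max()
                best = min(p for p in probes if crit[p] == best_val)
            rows.append(sub.loc[best].to_numpy())
        ids.append(ident)
    return ExpressionMatrix(ids, list(expr.sample_ids), np.vstack(rows))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns (samples) of a matrix.

    Every column is mapped onto the reference distribution formed by
    averaging the sorted columns, so all columns end with identical
    multisets of values.  Ties within a column receive the mean of the
    reference quantiles they span.
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    sorted_cols = np.sort(values, axis=0)
    reference = sorted_cols.mean(axis=1)
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty(n)
        ranked[order] = reference
        # average reference values across tied runs
        sorted_vals = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [n]])
        for s, e in zip(starts, ends):
            if e - s > 1:
                ranked[order[s:e]] = reference[s:e].mean()
        out[:, j] = ranked
    return out


def preprocess(expr: ExpressionMatrix, log2="auto", qnorm="off",
               pseudocount=1.0, missing_policy="row_mean") -> ExpressionMatrix:
    """Apply the standard transform chain: log2, quantile norm, imputation.

    ``log2='auto'`` transforms only when the matrix maximum exceeds
    ``LOG2_AUTO_THRESHOLD`` (linear-scale data); this makes the step
    idempotent on already-transformed matrices.  Missing values are imputed
    by row mean (or the offending samples dropped with
    ``missing_policy='drop_samples'``), since downstream Cox fitting needs
    complete cases.
    """
    if log2 not in ("auto", "on", "off"):
        raise ValueError(f"unknown log2 mode: {log2}")
    if qnorm not in ("on", "off"):
        raise ValueError(f"unknown qnorm mode: {qnorm}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    values = expr.values.copy()
    sample_ids = list(expr.sample_ids)

    finite_max = np.nanmax(values) if values.size else 0.0
    apply_log2 = log2 == "on" or (log2 == "auto" and finite_max > LOG2_AUTO_THRESHOLD)
    if apply_log2:
        shifted = values + pseudocount
        if np.nanmin(shifted) <= 0:
            raise ValueError("negative values remain after pseudocount; "
                             "cannot log2-transform")
        values = np.log2(shifted)

    n_missing = int(np.isnan(values).sum())
    if n_missing:
        if missing_policy == "row_mean":
            row_means = np.nanmean(values, axis=1)
            rows, cols = np.nonzero(np.isnan(values))
            values[rows, cols] = row_means[rows]
            logger.info("imputed %d missing values by row mean", n_missing)
        elif missing_policy == "drop_samples":
            keep = ~np.isnan(values).any(axis=0)
            dropped = [s for s, k in zip(sample_ids, keep) if not k]
            logger.info("dropped %d samples with missing values: %s",
                        len(dropped), ", ".join(dropped))
            values = values[:, keep]
            sample_ids = [s for s, k in zip(sample_ids, keep) if k]
        else:
            raise ValueError(f"unknown missing policy: {missing_policy}")
    if np.isnan(values).any():
        raise ValueError("matrix still contains missing values "
                         "(entire row missing?)")

    if qnorm == "on":
        values = quantile_normalize(values)

    return ExpressionMatrix(list(expr.probe_ids), sample_ids, values,
                            dict(expr.annotation))


def join_samples(expr: ExpressionMatrix, clinical: ClinicalTable):
    """Intersect expression and clinical samples, preserving expression order.

    Returns ``(expr, clinical, report)`` restricted to the common samples;
    ``report`` lists ids dropped from each side.
    """
    common = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    if not common:
        raise ValueError("no samples shared between expression and clinical")
    report = {
        "expression_only": [s for s in expr.sample_ids if s not in set(common)],
        "clinical_only": [s for s in clinical.sample_ids if s not in set(common)],
    }
    if report["expression_only"] or report["clinical_only"]:
        logger.info("sample join dropped %d expression / %d clinical samples",
                    len(report["expression_only"]), len(report["clinical_only"]))
    return expr.subset_samples(common), clinical.subset(common), report
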