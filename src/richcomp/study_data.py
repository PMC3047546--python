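"""Data model, I/O and validation for multi-site plot-level response tables.

The canonical table has one row per experimental plot with columns
``site, block, plot, richness, composition, anpp`` (an optional
``composition_code`` column carries cross-site composition identity).
Blocks are nested in sites; input files may reuse block labels across
sites, so block identity is always interpreted site-locally.
"""
from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace

import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column names, in file order
REQUIRED_COLUMNS = ("site", "block", "plot", "richness", "composition", "anpp")


class SchemaError(ValueError):
    """Input file does not expose the required columns."""


class RecordValidationError(ValueError):
    """A row violates a field-level invariant."""


class CompositionConflictError(ValueError):
    """One composition label is bound to more than one species set in a site."""


class EmptyDataError(ValueError):
    """No usable rows remain."""


@dataclass(frozen=True)
class PlotRecord:
    """One experimental plot: design coordinates plus the ANPP response.

    ``anpp`` is ``None`` when the response is missing -- never 0.
    ``composition_code`` is a dense global integer shared by identical
    species sets across sites; it is ``None`` until deduplication runs.
    """

    site_id: str
    block_id: str
    plot_id: str
    richness: int
    composition_label: str
    anpp: float | None = None
    composition_code: int | None = None

    @property
    def is_missing(self) -> bool:
        return self.anpp is None

    @property
    def global_block(self) -> str:
        """Site-prefixed block label, unique across the whole dataset."""
        return f"{self.site_id}:{self.block_id}"


def validate_records(records: Sequence[PlotRecord]) -> None:
    """Check field invariants; raise :class:`RecordValidationError` on the
    first violating row (1-based index)."""
    if not records:
        raise EmptyDataError("no records to validate")
    code_richness: dict[int, int] = {}
    for i, rec in enumerate(records, start=1):
        if rec.richness < 1:
            raise RecordValidationError(f"row {i}: richness {rec.richness} < 1")
        if rec.anpp is not None and rec.anpp < 0:
            raise RecordValidationError(f"row {i}: negative anpp {rec.anpp}")
        if rec.composition_code is not None:
            prev = code_richness.setdefault(rec.composition_code, rec.richness)
            if prev != rec.richness:
                raise RecordValidationError(
                    f"row {i}: composition code {rec.composition_code} carries "
                    f"richness {rec.richness}, elsewhere {prev}"
                )


def read_dataset(
    path,
    delimiter: str = ",",
    column_map: Mapping[str, str] | None = None,
) -> list[PlotRecord]:
    """Read a delimited plot table into validated :class:`PlotRecord`s.

    Parameters
    ----------
    path:
        File with a header row naming the six required columns.
    delimiter:
        Field separator; pass ``"\\t"`` for TSV.
    column_map:
        Optional mapping from canonical names (``site`` ...) to the names
        actually used in the file.

    Empty ``anpp`` cells become missing responses, not zeros.  Row order
    is preserved.
    """
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    colmap = dict(zip(REQUIRED_COLUMNS, REQUIRED_COLUMNS))
    if column_map:
        colmap.update(column_map)
    for canon, actual in colmap.items():
        if actual not in frame.columns:
            raise SchemaError(f"required column {actual!r} (for {canon!r}) not in header")
    has_codes = "composition_code" in frame.columns

    records: list[PlotRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = row._asdict()
        raw_anpp = row[colmap["anpp"]].strip()
        if raw_anpp in ("", "NA", "NaN", "nan"):
            anpp = None
        else:
            anpp = float(raw_anpp)
        try:
            richness = int(row[colmap["richness"]])
        except ValueError as exc:
            raise RecordValidationError(f"row {i}: unparseable richness") from exc
        code = None
        if has_codes and row["composition_code"].strip() != "":
            code = int(row["composition_code"])
        records.append(
            PlotRecord(
                site_id=str(row[colmap["site"]]),
                block_id=str(row[colmap["block"]]),
                plot_id=str(row[colmap["plot"]]),
                richness=richness,
                composition_label=str(row[colmap["composition"]]),
                anpp=anpp,
                composition_code=code,
            )
        )
    validate_records(records)
    return records


def write_dataset(records: Sequence[PlotRecord], path, delimiter: str = ",") -> None:
    """Write records in the canonical schema (round-trips with
    :func:`read_dataset` bit-identically on complete records)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "site": rec.site_id,
                "block": rec.block_id,
                "plot": rec.plot_id,
                "richness": rec.richness,
                "composition": rec.composition_label,
                "composition_code": "" if rec.composition_code is None else rec.composition_code,
                "anpp": "" if rec.anpp is None else repr(float(rec.anpp)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def _normalize_species(name: str) -> str:
    return name.strip().lower()


def species_table_to_sets(table: pd.DataFrame) -> dict:
    """Convert a long-format membership table into a label -> species-set map.

    Expected columns: ``composition_label`` (or ``composition``) and
    ``species``; an optional ``site`` column makes the binding site-local,
    in which case keys are ``(site, label)`` tuples.
    """
    label_col = "composition_label" if "composition_label" in table.columns else "composition"
    if label_col not in table.columns or "species" not in table.columns:
        raise SchemaError("membership table needs composition_label/composition and species columns")
    sets: dict = {}
    keyed_by_site = "site" in table.columns
    for _, row in table.iterrows():
        key = (str(row["site"]), str(row[label_col])) if keyed_by_site else str(row[label_col])
        sets.setdefault(key, set()).add(_normalize_species(str(row["species"])))
    return {k: frozenset(v) for k, v in sets.items()}


def deduplicate_compositions(
    records: Sequence[PlotRecord],
    species_sets: Mapping,
) -> list[PlotRecord]:
    """Assign global composition codes: identical species sets share one code
    regardless of site.

    ``species_sets`` maps either ``(site_id, composition_label)`` or bare
    ``composition_label`` keys to sets of species names (case-normalized
    before comparison).  Codes are dense integers 1..S in order of first
    appearance.  Idempotent: re-running yields identical codes.
    """
    normalized: dict = {}
    for key, members in species_sets.items():
        normalized[key] = frozenset(_normalize_species(m) for m in members)

    def lookup(rec: PlotRecord) -> frozenset:
        for key in ((rec.site_id, rec.composition_label), rec.composition_label):
            if key in normalized:
                return normalized[key]
        raise CompositionConflictError(
            f"no species set for composition {rec.composition_label!r} at site {rec.site_id!r}"
        )

    # a label may not denote two different sets (different sizes betray this
    # even without membership info) within one site
    seen_richness: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.site_id, rec.composition_label)
        prev = seen_richness.setdefault(key, rec.richness)
        if prev != rec.richness:
            raise CompositionConflictError(
                f"label {rec.composition_label!r} at site {rec.site_id!r} bound to "
                f"species sets of sizes {prev} and {rec.richness}"
            )

    codes: dict[frozenset, int] = {}
    out: list[PlotRecord] = []
    for rec in records:
        members = lookup(rec)
        if len(members) != rec.richness:
            raise CompositionConflictError(
                f"composition {rec.composition_label!r} at site {rec.site_id!r}: "
                f"species set size {len(members)} != richness {rec.richness}"
            )
        code = codes.setdefault(members, len(codes) + 1)
        out.append(replace(rec, composition_code=code))
    return out


@dataclass(frozen=True)
class DesignSummary:
    """Per-site design counts plus dataset-level totals."""

    per_site: pd.DataFrame
    n_sites: int
    n_blocks: int
    n_plots: int
    n_compositions_raw: int
    n_compositions_crossed: int


def summarize_design(records: Sequence[PlotRecord]) -> DesignSummary:
    """Count compositions, blocks, plots and richness levels per site.

    Totals are column sums; the crossed composition count collapses shared
    global codes (equal to the raw count when no codes are assigned).
    """
    if not records:
        raise EmptyDataError("cannot summarize an empty record collection")
    sites: dict[str, dict] = {}
    for rec in records:
        entry = sites.setdefault(
            rec.site_id,
            {"compositions": set(), "blocks": set(), "plots": set(), "richness": set()},
        )
        entry["compositions"].add(rec.composition_label)
        entry["blocks"].add(rec.block_id)
        entry["plots"].add(rec.plot_id)
        entry["richness"].add(rec.richness)
    rows = []
    for site_id in sorted(sites):
        entry = sites[site_id]
        rows.append(
            {
                "site_id": site_id,
                "n_compositions": len(entry["compositions"]),
                "n_blocks": len(entry["blocks"]),
                "n_plots": len(entry["plots"]),
                "richness_levels": tuple(sorted(entry["richness"])),
            }
        )
    per_site = pd.DataFrame(rows)
    codes = {rec.composition_code for rec in records}
    if None in codes:
        crossed = int(per_site["n_compositions"].sum())
    else:
        crossed = len(codes)
    return DesignSummary(
        per_site=per_site,
        n_sites=len(per_site),
        n_blocks=int(per_site["n_blocks"].sum()),
        n_plots=int(per_site["n_plots"].sum()),
        n_compositions_raw=int(per_site["n_compositions"].sum()),
        n_compositions_crossed=crossed,
    )


def complete_cases(records: Iterable[PlotRecord]) -> list[PlotRecord]:
    """Drop records with a missing response (listwise deletion).

    Logs the number of removed rows; raises :class:`EmptyDataError` if no
    complete rows remain.
    """
    records = list(records)
    kept = [rec for rec in records if not rec.is_missing]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("complete_cases: removed %d of %d records with missing anpp", dropped, len(records))
    if not kept:
        raise EmptyDataError("all records have missing anpp")
    return kept
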