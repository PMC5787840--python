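"""Direction-concordance logic.

Two flavours of agreement are checked:

* platform concordance — does the sign of a gene's change versus day 0 agree
  between RNA-seq and an orthogonal platform (RT-PCR-like) on every drought
  day (round 3 of the cascade);
* cross-species concordance — for each selected potato gene, do its
  Arabidopsis and rice homologues move in the same direction under drought?
  Published comparisons print one symbol per species, RELATIVE to the potato
  gene's response: an arrow for the same direction (up/down), a dash for no
  significant change, "nd" for no data, "No homologue", and an inequality
  sign for an opposite change.

Category bookkeeping: the mutually exclusive primary categories
(conserved in all three species / rice only / Arabidopsis only /
no-data-or-no-change) partition the gene list, while ``opposite_any`` counts
genes with at least one opposite-direction symbol and may overlap the
single-species conserved categories (a gene opposite in one species and
concordant in the other is tallied in both).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import pandas as pd

SAME_UP = "same_up"
SAME_DOWN = "same_down"
NO_CHANGE = "no_change"
NO_DATA = "no_data"
NO_HOMOLOGUE = "no_homologue"
OPPOSITE = "opposite"

SYMBOLS = (SAME_UP, SAME_DOWN, NO_CHANGE, NO_DATA, NO_HOMOLOGUE, OPPOSITE)

CONSERVED_ALL_THREE = "conserved_all_three"
CONSERVED_RICE_ONLY = "conserved_rice_only"
CONSERVED_ARABIDOPSIS_ONLY = "conserved_arabidopsis_only"
NO_DATA_OR_NONE = "no_data_or_none"

_SYMBOL_ALIASES = {
    "↗": SAME_UP,
    "↘": SAME_DOWN,
    "–": NO_CHANGE,  # en dash as printed
    "-": NO_CHANGE,
    "nd": NO_DATA,
    "no homologue": NO_HOMOLOGUE,
    "≠": OPPOSITE,
    "up": SAME_UP,
    "down": SAME_DOWN,
    "opp": OPPOSITE,
}

_CONSERVED = frozenset({SAME_UP, SAME_DOWN})


class ConcordanceError(ValueError):
    """Raised for unknown symbols or mismatched profiles."""


def parse_symbol(token: str) -> str:
    """Map a printed direction symbol (or ASCII alias) to the closed enum."""
    if token in SYMBOLS:
        return token
    key = str(token).strip().lower()
    if key in _SYMBOL_ALIASES:
        return _SYMBOL_ALIASES[key]
    if str(token).strip() in _SYMBOL_ALIASES:
        return _SYMBOL_ALIASES[str(token).strip()]
    raise ConcordanceError(f"unknown direction symbol {token!r}")


@dataclass(frozen=True)
class DirectionCall:
    """Direction of homologue response relative to the potato gene."""

    potato_gene_id: str
    arabidopsis: str
    rice: str

    def __post_init__(self) -> None:
        if not self.potato_gene_id:
            raise ConcordanceError("potato gene id must be non-empty")
        for sym in (self.arabidopsis, self.rice):
            if sym not in SYMBOLS:
                raise ConcordanceError(f"symbol {sym!r} not in {SYMBOLS}")


@dataclass
class ConcordanceTable:
    """Category tallies plus the per-gene assignments behind them."""

    counts: dict[str, int]
    opposite_any: int
    assignments: pd.DataFrame  # columns: category, has_opposite

    @property
    def n_calls(self) -> int:
        return len(self.assignments)

    def to_dict(self) -> dict:
        return {
            "n_calls": self.n_calls,
            "counts": dict(self.counts),
            "opposite_any": self.opposite_any,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def platform_concordant(a: pd.Series, b: pd.Series) -> bool:
    """True iff the two per-day direction profiles agree on every day.

    Profiles are Series indexed by drought day with values in
    {"up", "down", "none"}. ``none`` on either side is never concordant.
    """
    if set(a.index) != set(b.index):
        raise ConcordanceError(f"day sets differ: {sorted(a.index)} vs {sorted(b.index)}")
    for day in a.index:
        if a[day] == "none" or b[day] == "none" or a[day] != b[day]:
            return False
    return True


def classify_species_concordance(call: DirectionCall) -> str:
    """Primary (mutually exclusive) cross-species category of one call."""
    ara = call.arabidopsis in _CONSERVED
    rice = call.rice in _CONSERVED
    if ara and rice:
        return CONSERVED_ALL_THREE
    if rice:
        return CONSERVED_RICE_ONLY
    if ara:
        return CONSERVED_ARABIDOPSIS_ONLY
    return NO_DATA_OR_NONE


def tabulate_concordance(calls: list[DirectionCall]) -> ConcordanceTable:
    """Tally the primary categories and the overlapping opposite-direction count."""
    if not calls:
        raise ConcordanceError("no direction calls to tabulate")
    rows = []
    for call in calls:
        rows.append(
            {
                "potato_gene_id": call.potato_gene_id,
                "category": classify_species_concordance(call),
                "has_opposite": OPPOSITE in (call.arabidopsis, call.rice),
            }
        )
    assignments = pd.DataFrame(rows).set_index("potato_gene_id")
    counts = {
        cat: int((assignments["category"] == cat).sum())
        for cat in (
            CONSERVED_ALL_THREE,
            CONSERVED_RICE_ONLY,
            CONSERVED_ARABIDOPSIS_ONLY,
            NO_DATA_OR_NONE,
        )
    }
    return ConcordanceTable(
        counts=counts,
        opposite_any=int(assignments["has_opposite"].sum()),
        assignments=assignments,
    )


def read_direction_calls(path) -> list[DirectionCall]:
    """Read calls from a TSV with columns potato_gene, arabidopsis_symbol, rice_symbol."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["potato_gene", "arabidopsis_symbol", "rice_symbol"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ConcordanceError(f"direction-call table missing columns: {missing}")
    calls = []
    for i, row in frame.iterrows():
        try:
            calls.append(
                DirectionCall(
                    potato_gene_id=row["potato_gene"],
                    arabidopsis=parse_symbol(row["arabidopsis_symbol"]),
                    rice=parse_symbol(row["rice_symbol"]),
                )
            )
        except ConcordanceError as exc:
            raise ConcordanceError(f"row {i + 1} ({row['potato_gene']}): {exc}") from None
    return calls


def published_potato_calls() -> list[DirectionCall]:
    """The published cross-species direction calls for the 23 top-ranking
    potato drought-responsive genes (transcribed symbol table shipped with
    the package)."""
    ref = importlib.resources.files("droughtdex.data").joinpath(
        "potato_homologue_directions.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        return read_direction_calls(path)


def write_concordance_table(table: ConcordanceTable, path) -> None:
    out = table.assignments.copy()
    out.to_csv(path, sep="\t")
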