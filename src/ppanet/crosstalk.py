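"""Cross-talk ranking over the stage-resolved networks.

A protein bridging two signalling pathways is a cross-talk candidate.  The
Cross-Talk Ranking Value (CTRV) of a protein counts, over all stage
networks, its associations whose partner belongs to a *different* pathway
class; the link value counts all its associations (its degree summed over
stages), so CTRV <= link always.  An association inside one pathway
changes neither endpoint's CTRV; a cross-pathway association increments
the CTRV of both endpoints.

Proteins known to act in several pathways are assigned to a single class —
the earliest-activated pathway under the stimulus (TNF before IL-1 before
MyD88-dependent before MyD88-independent TLR-4) — because multi-assignment
would dilute the CTRVs of genuine cross-talk candidates.  Negative
regulators keep their own class, so their bridging edges count as
cross-pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import RefinedPPAN
from .pool import CATALOGUES, ProteinPool, normalize_symbol

#: Activation order of the pathway classes under TNFα stress.
DEFAULT_PRECEDENCE = ("TNF", "IL1", "TLR4_MYD88_DEP", "TLR4_MYD88_IND", "NEG_REG")


@dataclass(frozen=True)
class PathwayAssignment:
    """Unique pathway class per protein plus the precedence used to pick it."""

    classes: dict[str, str]
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE

    def __getitem__(self, symbol: str) -> str:
        return self.classes[normalize_symbol(symbol)]

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.classes


def assign_pathways(
    pool: ProteinPool,
    extra_memberships: dict[str, set[str]] | None = None,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> PathwayAssignment:
    """Resolve every protein to exactly one pathway class.

    Memberships are the pool catalogue plus any extra classes supplied;
    a protein in several classes is assigned the earliest one under the
    precedence order.  A symbol with no membership at all is an error.
    """
    extra = {normalize_symbol(k): set(v) for k, v in (extra_memberships or {}).items()}
    extra_classes = set().union(*extra.values()) if extra else set()
    unknown = extra_classes - set(CATALOGUES)
    if unknown:
        raise ValueError(f"unknown pathway classes: {sorted(unknown)}")
    missing = sorted(extra_classes - set(precedence))
    if missing:
        raise ValueError(f"precedence does not cover classes: {missing}")
    rank = {c: i for i, c in enumerate(precedence)}
    classes: dict[str, str] = {}
    for symbol, catalogue in pool.entries:
        members = {catalogue} | extra.get(symbol, set())
        classes[symbol] = min(members, key=lambda c: rank[c])
    for symbol in extra:
        if symbol not in classes:
            members = extra[symbol]
            if not members:
                raise ValueError(f"symbol {symbol!r} has no pathway membership")
            classes[symbol] = min(members, key=lambda c: rank[c])
    return PathwayAssignment(classes=classes, precedence=tuple(precedence))


@dataclass
class CTRVTable:
    """Per-protein CTRV and link totals with per-stage breakdowns."""

    frame: pd.DataFrame  # index: symbol; columns: ctrv, link
    per_stage: pd.DataFrame  # columns: stage, symbol, ctrv, link

    def ctrv(self, symbol: str) -> int:
        return int(self.frame.loc[normalize_symbol(symbol), "ctrv"])

    def link(self, symbol: str) -> int:
        return int(self.frame.loc[normalize_symbol(symbol), "link"])

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        out = rank_crosstalk(self).reset_index()
        out.insert(0, "No.", range(1, len(out) + 1))
        out = out.rename(columns={"symbol": "Protein", "ctrv": "CTRV", "link": "Link"})
        out.to_csv(path, sep="\t", index=False)


def compute_ctrv(
    networks: list[RefinedPPAN], assignment: PathwayAssignment
) -> CTRVTable:
    """Count CTRV and link contributions per protein per stage and sum.

    Per stage, a protein's link contribution is its degree; its CTRV
    contribution is the number of incident edges whose other endpoint has a
    different pathway class.  Every network node must carry an assignment.
    """
    symbols = sorted({n for net in networks for n in net.graph.nodes})
    for s in symbols:
        if s not in assignment:
            raise KeyError(f"node {s!r} has no pathway assignment")
    rows = []
    for net in networks:
        for s in net.graph.nodes:
            link = net.graph.degree(s)
            ctrv = sum(
                1 for nb in net.graph.neighbors(s) if assignment[nb] != assignment[s]
            )
            rows.append({"stage": net.stage, "symbol": s, "ctrv": ctrv, "link": link})
    per_stage = pd.DataFrame(rows, columns=["stage", "symbol", "ctrv", "link"])
    if per_stage.empty:
        totals = pd.DataFrame(columns=["ctrv", "link"], dtype=int)
    else:
        totals = per_stage.groupby("symbol")[["ctrv", "link"]].sum()
    # proteins assigned but isolated everywhere get explicit zeros
    for s in assignment.classes:
        if s not in totals.index:
            totals.loc[s] = [0, 0]
    totals = totals.astype(int).sort_index()
    return CTRVTable(frame=totals, per_stage=per_stage)


def rank_crosstalk(table: CTRVTable, per_stage: bool = False) -> pd.DataFrame:
    """Rank proteins by CTRV descending; ties by link descending, then symbol.

    With ``per_stage=True`` each stage's breakdown is ranked separately
    (the stage-wise top-candidates view).
    """
    if per_stage:
        if table.per_stage.empty:
            return table.per_stage.copy()
        return (
            table.per_stage.sort_values(
                ["stage", "ctrv", "link", "symbol"],
                ascending=[True, False, False, True],
            ).reset_index(drop=True)
        )
    frame = table.frame.copy()
    frame.index.name = "symbol"
    frame = frame.sort_values(
        ["ctrv", "link", "symbol"], ascending=[False, False, True]
    )
    return frame[["ctrv", "link"]]


def top_per_stage(table: CTRVTable, n: int = 5) -> pd.DataFrame:
    """Top-n cross-talk candidates in each stage (one row per stage)."""
    ranked = rank_crosstalk(table, per_stage=True)
    rows = []
    for stage, grp in ranked.groupby("stage", sort=True):
        rows.append(
            {"stage": stage, "top": " ".join(grp["symbol"].head(n).tolist())}
        )
    return pd.DataFrame(rows)


def select_core(
    table: CTRVTable, k: int, receptors: frozenset[str] | None = None
) -> dict[str, list[str]]:
    """Select the bow-tie core: the top-k proteins of the CTRV ranking.

    Returns the three-part labelling used for export: receptors on the
    input side, the core, and the remainder.
    """
    if not 0 <= k <= len(table):
        raise ValueError(f"k={k} outside 0..{len(table)}")
    ranking = list(rank_crosstalk(table).index)
    core = ranking[:k]
    receptors = receptors or frozenset()
    inputs = sorted(s for s in ranking if s in receptors and s not in core)
    rest = [s for s in ranking if s not in core and s not in inputs]
    return {"input": inputs, "core": core, "other": rest}
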