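"""Vote-based multi-study IBD gene metasignature and cross-species overlap.

Each input "bioset" is one study's differential-expression list: (gene,
signed fold change, p-value). Lists are filtered to |FC| >= 1.5 and
p <= 0.05; a gene joins the metasignature when it is perturbed in at least
9 of the 18 filtered lists, with a mean fold-change magnitude >= 2 over the
lists in which it votes, consistently in one direction. Overlap between a
mouse DE gene set and the human metasignature is taken through an ortholog
map and scored with a hypergeometric enrichment test.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Bioset",
    "MetasigConfig",
    "OrthologMap",
    "OverlapResult",
    "read_bioset",
    "write_bioset",
    "filter_bioset",
    "derive_metasignature",
    "read_ortholog_map",
    "overlap",
]


@dataclasses.dataclass
class Bioset:
    """One study's gene list: records (gene, fc, p) with signed fold change.

    ``fc`` carries direction in its sign and magnitude >= 0 in its absolute
    value (e.g. -2.5 means 2.5-fold down). Genes are unique within a bioset.
    """

    study_id: str
    records: pd.DataFrame  # columns: gene, fc, p

    def __post_init__(self) -> None:
        r = self.records
        required = {"gene", "fc", "p"}
        if not required.issubset(r.columns):
            raise ValueError(f"bioset {self.study_id}: missing columns {required - set(r.columns)}")
        if r["gene"].duplicated().any():
            dupes = r.loc[r["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"bioset {self.study_id}: duplicate genes {dupes}")
        if (r["fc"] == 0).any():
            raise ValueError(f"bioset {self.study_id}: zero fold change")
        if ((r["p"] < 0) | (r["p"] > 1)).any():
            raise ValueError(f"bioset {self.study_id}: p-values outside [0, 1]")
        self.records = r.reset_index(drop=True)


@dataclasses.dataclass
class MetasigConfig:
    """Thresholds for per-list filtering and cross-list voting."""

    list_fc_min: float = 1.5
    list_p_max: float = 0.05
    min_votes: int = 9
    n_lists: int = 18
    mean_fc_min: float = 2.0
    direction_rule: Literal["strict_all", "majority"] = "strict_all"

    def __post_init__(self) -> None:
        if not (1 <= self.min_votes <= self.n_lists):
            raise ValueError("min_votes must lie in [1, n_lists]")
        if min(self.list_fc_min, self.list_p_max, self.mean_fc_min) <= 0:
            raise ValueError("thresholds must be positive")


def read_bioset(path: str | Path, study_id: str | None = None) -> Bioset:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    return Bioset(study_id or path.stem, df[["gene", "fc", "p"]])


def write_bioset(b: Bioset, path: str | Path) -> None:
    b.records.to_csv(path, sep="\t", index=False)


def filter_bioset(b: Bioset, cfg: MetasigConfig | None = None) -> Bioset:
    """Keep records with |fc| >= list_fc_min and p <= list_p_max (both inclusive)."""
    cfg = cfg or MetasigConfig()
    r = b.records
    keep = (r["fc"].abs() >= cfg.list_fc_min) & (r["p"] <= cfg.list_p_max)
    return Bioset(b.study_id, r.loc[keep].reset_index(drop=True))


def derive_metasignature(
    biosets: Iterable[Bioset], cfg: MetasigConfig | None = None
) -> pd.DataFrame:
    """Vote genes across filtered biosets into a consensus metasignature.

    A gene is admitted when (i) it appears ("votes") in at least ``min_votes``
    filtered lists, (ii) its mean |fc| over the voting lists is >=
    ``mean_fc_min``, and (iii) its direction is consistent: under
    ``strict_all`` every voting occurrence must share one sign, under
    ``majority`` the majority sign wins (ties fail). Returns a DataFrame
    (gene, votes, mean_fc, direction) sorted by votes then mean_fc
    descending, ties broken by gene id.
    """
    cfg = cfg or MetasigConfig()
    biosets = list(biosets)
    if len(biosets) < cfg.min_votes:
        raise ValueError(
            f"{len(biosets)} biosets provided but min_votes={cfg.min_votes}"
        )
    filtered = [filter_bioset(b, cfg) for b in biosets]
    long = pd.concat(
        [f.records.assign(study=f.study_id) for f in filtered], ignore_index=True
    )
    rows = []
    for gene, grp in long.groupby("gene", sort=False):
        votes = len(grp)
        if votes < cfg.min_votes:
            continue
        mean_fc = float(grp["fc"].abs().mean())
        if mean_fc < cfg.mean_fc_min:
            continue
        n_up = int((grp["fc"] > 0).sum())
        n_down = votes - n_up
        if cfg.direction_rule == "strict_all":
            if n_up and n_down:
                continue
            direction = "up" if n_up else "down"
        else:
            if n_up == n_down:
                continue
            direction = "up" if n_up > n_down else "down"
        rows.append((gene, votes, mean_fc, direction))
    out = pd.DataFrame(rows, columns=["gene", "votes", "mean_fc", "direction"])
    out = out.sort_values(
        ["votes", "mean_fc", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return out


@dataclasses.dataclass
class OrthologMap:
    """Gene correspondence between two species (e.g. mouse -> human).

    One-to-many orthologs are resolved to the first-listed pair by default;
    ``keep_all`` retains every pair (a source gene then maps to a set).
    Genes absent from the map are explicitly unmapped.
    """

    pairs: pd.DataFrame  # columns: source, target
    keep_all: bool = False

    def __post_init__(self) -> None:
        if not {"source", "target"}.issubset(self.pairs.columns):
            raise ValueError("ortholog map needs 'source' and 'target' columns")
        self.pairs = self.pairs.drop_duplicates().reset_index(drop=True)

    def map_genes(self, genes: Iterable[str]) -> dict[str, list[str]]:
        """Map source genes to target genes; unmapped genes are omitted."""
        genes = set(genes)
        sub = self.pairs[self.pairs["source"].isin(genes)]
        if not self.keep_all:
            sub = sub.drop_duplicates(subset="source", keep="first")
        out: dict[str, list[str]] = {}
        for src, tgt in zip(sub["source"], sub["target"]):
            out.setdefault(src, []).append(tgt)
        return out

    def mapped_set(self, genes: Iterable[str]) -> set[str]:
        return {t for ts in self.map_genes(genes).values() for t in ts}


def read_ortholog_map(path: str | Path, keep_all: bool = False) -> OrthologMap:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={df.columns[0]: "source", df.columns[1]: "target"})
    return OrthologMap(df[["source", "target"]], keep_all=keep_all)


@dataclasses.dataclass
class OverlapResult:
    n_set_a: int
    n_set_b: int
    n_universe: int
    n_overlap: int
    p_value: float
    overlap_genes: list[str]
    n_concordant: int | None = None


def overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    orthologs: OrthologMap | None,
    universe: Iterable[str],
    directions_a: Mapping[str, str] | None = None,
    directions_b: Mapping[str, str] | None = None,
) -> OverlapResult:
    """Cross-species overlap of two gene sets with hypergeometric enrichment.

    ``set_a`` is translated through ``orthologs`` (pass None when both sets
    already share a namespace), both sets are restricted to ``universe``, and
    the enrichment p-value is the hypergeometric upper tail
    P(X >= n_overlap). When both sets carry per-gene directions, the
    direction-concordant overlap is counted as well.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    set_b = set(set_b)
    if orthologs is not None:
        mapping = orthologs.map_genes(set_a)
        mapped_a = {t for ts in mapping.values() for t in ts}
        dir_a_mapped: dict[str, str] = {}
        if directions_a is not None:
            for src, tgts in mapping.items():
                for t in tgts:
                    dir_a_mapped[t] = directions_a[src]
    else:
        mapped_a = set(set_a)
        dir_a_mapped = dict(directions_a) if directions_a else {}

    a = mapped_a & universe
    b = set_b & universe
    inter = a & b
    n, k_a, k_b, k = len(universe), len(a), len(b), len(inter)
    p = float(stats.hypergeom.sf(k - 1, n, k_a, k_b))

    n_conc = None
    if directions_a is not None and directions_b is not None:
        n_conc = sum(1 for g in inter if dir_a_mapped.get(g) == directions_b.get(g))
    return OverlapResult(
        n_set_a=k_a,
        n_set_b=k_b,
        n_universe=n,
        n_overlap=k,
        p_value=min(p, 1.0),
        overlap_genes=sorted(inter),
        n_concordant=n_conc,
    )
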