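"""Headline tables: family counts, duplication types, domain preference.

Percentages are count ratios displayed at 2 decimals with half-up
rounding; TSV outputs keep full precision.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .families import GeneFamily


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (1.005 -> 1.01), as printed tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 2) -> float | None:
    """Percentage at half-up display precision; None on zero denominator."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, ndigits)


def headline_ratios(counts: Mapping[str, tuple[int, int]]) -> dict[str, float | None]:
    """Named (numerator, denominator) pairs -> display percentages."""
    return {name: pct(num, den) for name, (num, den) in counts.items()}


def table1(families: Sequence[GeneFamily]) -> dict:
    """Young-family counts: per species (species-specific expansions) and
    per species combination (lineage-specific expansions), with totals."""
    ss: dict[str, int] = {}
    ls: dict[tuple[str, ...], int] = {}
    for fam in families:
        if not fam.is_young:
            continue
        kind, species = fam.expansion
        if kind == "species_specific":
            ss[species[0]] = ss.get(species[0], 0) + 1
        elif kind == "lineage_specific":
            ls[species] = ls.get(species, 0) + 1
    return {
        "species_specific": dict(sorted(ss.items())),
        "lineage_specific": {",".join(k): v for k, v in sorted(ls.items())},
        "species_specific_total": sum(ss.values()),
        "lineage_specific_total": sum(ls.values()),
        "young_total": sum(ss.values()) + sum(ls.values()),
    }


def table1_frame(families: Sequence[GeneFamily]) -> pd.DataFrame:
    t = table1(families)
    rows = [{"expansion": "species_specific", "species": sp, "n_families": n}
            for sp, n in t["species_specific"].items()]
    rows += [{"expansion": "lineage_specific", "species": k, "n_families": n}
             for k, n in t["lineage_specific"].items()]
    rows += [
        {"expansion": "species_specific", "species": "TOTAL", "n_families": t["species_specific_total"]},
        {"expansion": "lineage_specific", "species": "TOTAL", "n_families": t["lineage_specific_total"]},
    ]
    return pd.DataFrame(rows, columns=["expansion", "species", "n_families"])


def load_domain_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "domain"}
    if not need <= set(df.columns):
        raise ValueError(f"domain table must have columns {sorted(need)}")
    return df


def domain_summary(
    assignments: pd.DataFrame,
    families: Sequence[GeneFamily],
    expansion_kind: str,
    top_n: int = 20,
) -> dict:
    """Domain frequencies among young duplicate genes of one expansion kind.

    Counts are per gene occurrence (a domain counted once per gene carrying
    it). A domain's species occurrence is the number of species whose young
    duplicates of this kind carry it; the spectrum gives, for each
    occurrence level, the percentage of domains at that level. ``top``
    holds the ``top_n`` most frequent domains per species.
    """
    class_genes: dict[str, str] = {}
    for fam in families:
        if not fam.is_young or fam.expansion[0] != expansion_kind:
            continue
        for g, sp in fam.members.items():
            if sp in fam.expansion[1]:
                class_genes[g] = sp
    known = assignments[assignments["gene_id"].isin(class_genes)]
    skipped = int((~assignments["gene_id"].isin(class_genes)).sum())
    counts: dict[str, dict[str, int]] = {}
    for r in known.drop_duplicates(["gene_id", "domain"]).itertuples():
        sp = class_genes[r.gene_id]
        counts.setdefault(r.domain, {})[sp] = counts.setdefault(r.domain, {}).get(sp, 0) + 1
    n_domains = len(counts)
    occurrence = {dom: len(per_sp) for dom, per_sp in counts.items()}
    spectrum: dict[int, dict] = {}
    if n_domains:
        levels = sorted(set(occurrence.values()))
        for lvl in levels:
            n = sum(1 for v in occurrence.values() if v == lvl)
            spectrum[lvl] = {"n_domains": n, "pct": pct(n, n_domains)}
    species = sorted({sp for per_sp in counts.values() for sp in per_sp})
    top = {
        sp: sorted(
            ((dom, per_sp[sp]) for dom, per_sp in counts.items() if sp in per_sp),
            key=lambda t: (-t[1], t[0]),
        )[:top_n]
        for sp in species
    }
    return {
        "n_domains": n_domains,
        "per_domain_species_counts": counts,
        "occurrence": occurrence,
        "spectrum": spectrum,
        "top": top,
        "n_assignments_skipped": skipped,
    }
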