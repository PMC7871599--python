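"""Chromosomal window profiles of young duplicate genes.

Each chromosome is divided into fixed-size windows (default 1 Mb); a gene
belongs to the window containing its start coordinate. For a class of
genes (e.g. the species-specific young duplicates of one species) the
profile records the class gene count, the total annotated gene count and
their ratio per window. The per-chromosome correlation between the
species-specific and lineage-specific count vectors is Pearson's r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_io import GenomeSet


@dataclass
class WindowProfile:
    species: str
    chromosome: str
    n_young: np.ndarray  # per-window class gene counts
    n_total: np.ndarray  # per-window annotated gene counts

    @property
    def density(self) -> np.ndarray:
        """Class genes over all genes per window (0 where the window is empty)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(self.n_total > 0, self.n_young / np.maximum(self.n_total, 1), 0.0)
        return d

    def density_per_mb(self, window_size: int) -> np.ndarray:
        """Alternative density: class genes per megabase of window."""
        return self.n_young / (window_size / 1e6)


def window_profile(
    genomes: GenomeSet,
    class_genes: Iterable[str],
    window_size: int = 1_000_000,
) -> list[WindowProfile]:
    """Profiles for every (species, chromosome) touched by the class genes.

    Windows run from 0 up to the last gene-containing window of the
    chromosome; window index = floor(start / window_size).
    """
    class_set = set(class_genes)
    profiles = []
    species_touched = sorted({genomes[g].species for g in class_set})
    for sp in species_touched:
        for chrom in genomes.chromosomes(sp):
            genes = genomes.chromosome_genes(sp, chrom)
            if not genes:
                continue
            last = max(g.start // window_size for g in genes)
            n_young = np.zeros(last + 1, dtype=int)
            n_total = np.zeros(last + 1, dtype=int)
            for g in genes:
                w = g.start // window_size
                n_total[w] += 1
                if g.gene_id in class_set:
                    n_young[w] += 1
            profiles.append(WindowProfile(sp, chrom, n_young, n_total))
    return profiles


def correlate(counts_ss: Sequence[float], counts_ls: Sequence[float]) -> float | None:
    """Pearson r between two same-length window count vectors.

    Returns None when either vector is constant (the coefficient is
    undefined); requires at least 3 windows.
    """
    a, b = np.asarray(counts_ss, float), np.asarray(counts_ls, float)
    if a.shape != b.shape:
        raise ValueError("window vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 windows")
    if a.std() == 0 or b.std() == 0:
        return None
    r, _ = sps.pearsonr(a, b)
    return float(r)


def profiles_to_frame(profiles: Iterable[WindowProfile], label: str = "young") -> pd.DataFrame:
    rows = []
    for p in profiles:
        dens = p.density
        for w in range(len(p.n_total)):
            rows.append({
                "species": p.species, "chromosome": p.chromosome, "window": w,
                f"n_{label}": int(p.n_young[w]), "n_total": int(p.n_total[w]),
                "density": float(dens[w]),
            })
    return pd.DataFrame(rows, columns=["species", "chromosome", "window",
                                       f"n_{label}", "n_total", "density"])


def correlation_table(
    profiles_ss: Sequence[WindowProfile],
    profiles_ls: Sequence[WindowProfile],
) -> pd.DataFrame:
    """Per-chromosome Pearson r between the two expansion classes."""
    ls_by_key = {(p.species, p.chromosome): p for p in profiles_ls}
    rows = []
    for p in profiles_ss:
        q = ls_by_key.get((p.species, p.chromosome))
        if q is None:
            continue
        n = max(len(p.n_young), len(q.n_young))
        a = np.pad(p.n_young, (0, n - len(p.n_young)))
        b = np.pad(q.n_young, (0, n - len(q.n_young)))
        r = correlate(a, b) if n >= 3 else None
        rows.append({"species": p.species, "chromosome": p.chromosome,
                     "n_windows": n, "pearson_r": np.nan if r is None else r})
    return pd.DataFrame(rows, columns=["species", "chromosome", "n_windows", "pearson_r"])
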