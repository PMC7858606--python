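"""Gene set enrichment analysis against a ranked signature.

Compares protein signatures (as gene sets) with a ranked mRNA
t-statistic signature using the weighted Kolmogorov-Smirnov running-sum
statistic: walking down the ranked list, hits increment the sum by
``|score|^p / sum over set of |score|^p`` and misses decrement it by
``1/(N - |set|)``; the enrichment score (ES) is the extremum of the
walk.  Significance comes from a gene-set permutation null (size-matched
random draws from the ranked genes); the normalised ES (NES) divides by
the mean same-sign null magnitude, and FDR uses the pooled-NES
procedure when several sets are tested together.

Standard GMT (gene sets) and RNK (ranked scores) interchange formats
are read and written losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class GseaError(ValueError):
    pass


@dataclass
class RankedSignature:
    """Genes ordered by descending score; ties broken by gene id."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise GseaError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise GseaError("duplicate gene ids in ranked signature")
        self.scores = np.asarray(self.scores, dtype=float)

    @classmethod
    def from_scores(cls, scores: dict[str, float] | pd.Series) -> "RankedSignature":
        s = pd.Series(scores)
        if s.index.duplicated().any():
            dup = s.index[s.index.duplicated()][0]
            raise GseaError(f"duplicate gene id {dup!r}")
        order = sorted(s.index, key=lambda g: (-s[g], g))
        return cls(genes=[str(g) for g in order], scores=s.loc[order].to_numpy())

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSet:
    name: str
    members: frozenset
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise GseaError(f"gene set {self.name!r} is empty")
        self.members = frozenset(str(m) for m in self.members)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr: float
    core_genes: list[str]
    n_permutations: int
    seed: int
    running_sum: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# ES walk
# ---------------------------------------------------------------------------

def enrichment_score(
    signature: RankedSignature, gene_set: GeneSet, weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS running sum, its extremum (ES) and the leading edge.

    The leading edge contains the set members at or before the extremum
    position for a positive ES, and at or after it for a negative ES.
    """
    hits = np.fromiter(
        (g in gene_set.members for g in signature.genes), dtype=bool,
        count=len(signature),
    )
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise GseaError(
            f"gene set {gene_set.name!r} has no members in the ranked list"
        )
    N = len(signature)
    if n_hits == N:
        raise GseaError("gene set covers the whole ranked list")
    w = np.abs(signature.scores) ** weight
    hit_total = w[hits].sum()
    steps = np.where(hits, w / hit_total if hit_total > 0 else 1.0 / n_hits,
                     -1.0 / (N - n_hits))
    running = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(signature.genes[: i_ext + 1], hits[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(signature.genes[i_ext:], hits[i_ext:]) if h]
    return es, running, leading


def _null_es(
    signature: RankedSignature,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    weight: float,
) -> np.ndarray:
    """Size-matched gene-label permutation null of the ES."""
    N = len(signature)
    w = np.abs(signature.scores) ** weight
    out = np.empty(n_perm)
    miss_step = -1.0 / (N - set_size)
    for i in range(n_perm):
        idx = rng.choice(N, size=set_size, replace=False)
        hits = np.zeros(N, dtype=bool)
        hits[idx] = True
        hit_total = w[idx].sum()
        steps = np.where(hits, w / hit_total if hit_total > 0 else 1.0 / set_size,
                         miss_step)
        running = np.cumsum(steps)
        out[i] = running[np.argmax(np.abs(running))]
    return out


def gsea_test(
    signature: RankedSignature,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Permutation test of one gene set against the ranked signature.

    NES = ES / mean(|null ES| of the matching sign); the nominal p-value
    is the one-sided fraction of same-sign null ES at least as extreme.
    Single-set FDR equals the nominal p (no pooling possible).
    """
    results = gsea_multi(signature, [gene_set], n_perm=n_perm, seed=seed, weight=weight)
    return results[0]


def gsea_multi(
    signature: RankedSignature,
    gene_sets: list[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> list[EnrichmentResult]:
    """Test several gene sets; FDR by the pooled-NES procedure.

    All null ES values (normalised per set) are pooled; the FDR of a set
    with NES* is the ratio of the null tail fraction beyond NES* to the
    observed tail fraction, clipped to [0, 1].
    """
    if n_perm < 100:
        raise GseaError("need n_perm >= 100")
    in_list = set(signature.genes)
    rng = np.random.default_rng(seed)
    obs: list[tuple[float, np.ndarray, list[str]]] = []
    nulls: list[np.ndarray] = []
    for gs in gene_sets:
        overlap = gs.members & in_list
        if len(overlap) > len(signature):
            raise GseaError(f"gene set {gs.name!r} larger than the ranked list")
        es, running, leading = enrichment_score(signature, gs, weight)
        obs.append((es, running, leading))
        nulls.append(_null_es(signature, len(overlap), n_perm, rng, weight))

    nes_obs = np.empty(len(gene_sets))
    nes_null: list[np.ndarray] = []
    p_vals = np.empty(len(gene_sets))
    for i, ((es, _running, _leading), null) in enumerate(zip(obs, nulls)):
        pos = null[null >= 0]
        neg = null[null < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        if es >= 0:
            p_vals[i] = float(np.mean(pos >= es)) if pos.size else 1.0
            nes_obs[i] = es / mean_pos if pos.size else np.nan
        else:
            p_vals[i] = float(np.mean(neg <= es)) if neg.size else 1.0
            nes_obs[i] = -abs(es) / mean_neg if neg.size else np.nan
        nn = np.where(null >= 0, null / mean_pos, null / mean_neg)
        nes_null.append(nn)

    pooled = np.concatenate(nes_null)
    results = []
    for i, gs in enumerate(gene_sets):
        nes = nes_obs[i]
        if np.isnan(nes):
            fdr = 1.0
        elif nes >= 0:
            null_tail = np.mean(pooled[pooled >= 0] >= nes) if np.any(pooled >= 0) else 0.0
            obs_tail = np.mean(nes_obs[nes_obs >= 0] >= nes)
            fdr = float(null_tail / obs_tail) if obs_tail > 0 else 0.0
        else:
            null_tail = np.mean(pooled[pooled < 0] <= nes) if np.any(pooled < 0) else 0.0
            obs_tail = np.mean(nes_obs[nes_obs < 0] <= nes)
            fdr = float(null_tail / obs_tail) if obs_tail > 0 else 0.0
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                es=obs[i][0],
                nes=float(nes),
                p_value=float(p_vals[i]),
                fdr=float(min(max(fdr, 0.0), 1.0)),
                core_genes=obs[i][2],
                n_permutations=n_perm,
                seed=seed,
                running_sum=obs[i][1],
            )
        )
    return results


# ---------------------------------------------------------------------------
# GMT / RNK interchange
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise GseaError(f"{path}:{ln}: GMT line needs name, description, members")
        name, desc, *members = parts
        members = [m for m in members if m]
        if not members:
            raise GseaError(f"{path}:{ln}: gene set {name!r} has no members")
        sets.append(GeneSet(name=name, description=desc, members=frozenset(members)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.description, *sorted(s.members)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_rnk(path: str | Path) -> RankedSignature:
    scores: dict[str, float] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise GseaError(f"{path}:{ln}: RNK line needs 'gene<TAB>score'")
        gene, score = parts
        if gene in scores:
            raise GseaError(f"{path}:{ln}: duplicate gene {gene!r}")
        try:
            scores[gene] = float(score)
        except ValueError as exc:
            raise GseaError(f"{path}:{ln}: non-numeric score {score!r}") from exc
    return RankedSignature.from_scores(scores)


def write_rnk(signature: RankedSignature, path: str | Path) -> None:
    lines = [f"{g}\t{s:.10g}" for g, s in zip(signature.genes, signature.scores)]
    Path(path).write_text("\n".join(lines) + "\n")
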