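"""Microsatellite genotypes and Weir–Cockerham F_ST estimation.

Genotypes live in a :class:`GenotypeDataset`: diploid, multi-allelic calls for
individuals grouped into populations, read from and written to plain-text
GENEPOP files. Differentiation is estimated with the Weir & Cockerham (1984)
moment estimator theta: per-locus variance components ``a`` (among
populations), ``b`` (among individuals within populations) and ``c`` (within
individuals) are accumulated over alleles and loci, and the multilocus
estimate is the ratio of sums. Confidence intervals come from resampling loci
(percentile bootstrap by default, delete-one jackknife as an option).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeDataset",
    "FstResult",
    "read_genepop",
    "write_genepop",
    "wc_theta_locus",
    "multilocus_theta",
    "pairwise_fst",
    "bootstrap_fst_ci",
    "jackknife_fst_ci",
    "fst_analysis",
]

MISSING = 0  # allele code reserved for missing data


class GenepopFormatError(ValueError):
    """Raised when a GENEPOP file violates the dialect."""


class NoVariationError(ValueError):
    """Raised when theta is requested for data with no allelic variation."""


@dataclass
class GenotypeDataset:
    """Diploid genotypes for individuals grouped into populations.

    Parameters
    ----------
    populations
        Ordered population labels.
    loci
        Ordered locus names.
    individual_ids
        Unique individual identifiers, ordered.
    pop_index
        For each individual, the index of its population in ``populations``.
    calls
        Integer array ``(n_individuals, n_loci, 2)`` of allele codes
        (positive integers; 0 marks a missing call). Both alleles of a
        genotype are missing together.
    """

    populations: list[str]
    loci: list[str]
    individual_ids: list[str]
    pop_index: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.pop_index = np.asarray(self.pop_index, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n = len(self.individual_ids)
        if self.calls.shape != (n, len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {len(self.loci)} loci x 2"
            )
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        if self.pop_index.shape != (n,):
            raise ValueError("pop_index must have one entry per individual")
        if n and (self.pop_index.min() < 0 or self.pop_index.max() >= len(self.populations)):
            raise ValueError("pop_index out of range")
        half_missing = (self.calls == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("half-missing genotypes are not allowed")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def pop_sizes(self) -> dict[str, int]:
        counts = np.bincount(self.pop_index, minlength=self.n_populations)
        return dict(zip(self.populations, counts.tolist()))

    def subset_populations(self, pops: Sequence[str]) -> "GenotypeDataset":
        """Restrict to the given populations (kept in the given order)."""
        missing = [p for p in pops if p not in self.populations]
        if missing:
            raise KeyError(f"unknown populations: {missing}")
        old_idx = {p: i for i, p in enumerate(self.populations)}
        wanted = np.array([old_idx[p] for p in pops])
        mask = np.isin(self.pop_index, wanted)
        remap = {old_idx[p]: j for j, p in enumerate(pops)}
        new_pop_index = np.array([remap[i] for i in self.pop_index[mask]], dtype=np.int64)
        return GenotypeDataset(
            populations=list(pops),
            loci=list(self.loci),
            individual_ids=[i for i, m in zip(self.individual_ids, mask) if m],
            pop_index=new_pop_index,
            calls=self.calls[mask],
        )


# ---------------------------------------------------------------------------
# GENEPOP I/O
# ---------------------------------------------------------------------------

def _detect_width(tokens: Iterable[str], path: str) -> int:
    widths = {len(t) for t in tokens}
    if widths <= {4}:
        return 2
    if widths <= {6}:
        return 3
    raise GenepopFormatError(
        f"{path}: mixed or invalid genotype token lengths {sorted(widths)}; "
        "expected uniformly 4 (2-digit alleles) or 6 (3-digit)"
    )


def read_genepop(path: str | Path, pop_names: Sequence[str] | None = None) -> GenotypeDataset:
    """Read a GENEPOP file.

    The dialect: a title line, locus names (one per line or comma-separated
    on one line), then population blocks introduced by a line reading "POP"
    (any case), each individual on a line ``id , g1 g2 ...`` with genotypes
    encoded as 2- or 3-digit allele pairs (``0101`` / ``001001``); an
    all-zero token is a missing call. Allele-code width is detected from
    token length and must be consistent across the file.

    By GENEPOP convention the label of a population is the id of the last
    individual in its block; pass ``pop_names`` to override.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GenepopFormatError(f"{path}: too short to be a GENEPOP file")

    # locus names: everything between the title and the first POP line
    pop_line_idx = [
        i for i, ln in enumerate(lines) if ln.strip().upper() == "POP"
    ]
    if not pop_line_idx:
        raise GenepopFormatError(f"{path}: no POP section")
    first_pop = pop_line_idx[0]
    loci: list[str] = []
    for ln in lines[1:first_pop]:
        loci.extend(t.strip() for t in ln.split(",") if t.strip())
    if not loci:
        raise GenepopFormatError(f"{path}: no locus names before first POP")

    blocks: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] | None = None
    all_tokens: list[str] = []
    for lineno, ln in enumerate(lines[first_pop:], start=first_pop + 1):
        stripped = ln.strip()
        if not stripped:
            continue
        if stripped.upper() == "POP":
            current = []
            blocks.append(current)
            continue
        if current is None:  # pragma: no cover - guarded by first_pop
            raise GenepopFormatError(f"{path}:{lineno}: data before first POP")
        if "," not in stripped:
            raise GenepopFormatError(f"{path}:{lineno}: expected 'id , genotypes'")
        ind_id, _, geno_part = stripped.partition(",")
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise GenepopFormatError(
                f"{path}:{lineno}: {len(tokens)} genotype tokens for {len(loci)} loci"
            )
        for t in tokens:
            if not t.isdigit() or len(t) % 2:
                raise GenepopFormatError(
                    f"{path}:{lineno}: bad genotype token {t!r} (odd or non-numeric)"
                )
        all_tokens.extend(tokens)
        current.append((ind_id.strip(), tokens))

    width = _detect_width(all_tokens, str(path))

    populations: list[str] = []
    individual_ids: list[str] = []
    pop_index: list[int] = []
    calls: list[list[list[int]]] = []
    seen_ids: set[str] = set()
    for b, block in enumerate(blocks):
        if not block:
            raise GenepopFormatError(f"{path}: empty POP block #{b + 1}")
        if pop_names is not None:
            label = pop_names[b]
        else:
            label = block[-1][0]
        populations.append(label)
        for k, (ind_id, tokens) in enumerate(block, start=1):
            uid = ind_id
            if uid in seen_ids:
                uid = f"{ind_id}_{b + 1}.{k}"
            seen_ids.add(uid)
            individual_ids.append(uid)
            pop_index.append(b)
            row = []
            for t in tokens:
                a1, a2 = int(t[:width]), int(t[width:])
                if (a1 == 0) != (a2 == 0):
                    a1 = a2 = 0  # half-missing collapses to missing
                row.append([a1, a2])
            calls.append(row)

    return GenotypeDataset(
        populations=populations,
        loci=loci,
        individual_ids=individual_ids,
        pop_index=np.array(pop_index),
        calls=np.array(calls),
    )


def write_genepop(dataset: GenotypeDataset, path: str | Path, title: str = "thermocline export") -> None:
    """Write a GENEPOP file (3-digit allele encoding)."""
    path = Path(path)
    if (dataset.calls > 999).any():
        raise ValueError("allele codes above 999 cannot be written as GENEPOP")
    out = [title]
    out.extend(dataset.loci)
    for p in range(dataset.n_populations):
        out.append("POP")
        for i in np.flatnonzero(dataset.pop_index == p):
            toks = [
                f"{a1:03d}{a2:03d}" for a1, a2 in dataset.calls[i]
            ]
            out.append(f"{dataset.individual_ids[i]} , " + " ".join(toks))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta
# ---------------------------------------------------------------------------

def _locus_components(calls: np.ndarray, pop_index: np.ndarray, n_pops: int) -> tuple[float, float, float]:
    """Summed WC84 components (a, b, c) over alleles for one locus.

    ``calls``: (n_individuals, 2) allele codes with 0 = missing.
    Individuals missing at the locus are dropped locus-wise.
    """
    ok = calls[:, 0] != MISSING
    calls = calls[ok]
    pop_index = pop_index[ok]
    # populations with at least one genotype at this locus
    counts = np.bincount(pop_index, minlength=n_pops)
    keep = np.flatnonzero(counts > 0)
    r = keep.size
    if r < 2:
        raise NoVariationError("need >= 2 populations with data at the locus")
    remap = -np.ones(n_pops, dtype=np.int64)
    remap[keep] = np.arange(r)
    g = remap[pop_index]
    n_i = counts[keep].astype(float)

    alleles = np.unique(calls)
    nbar = n_i.mean()
    nsum = n_i.sum()
    nc = (nsum - (n_i**2).sum() / nsum) / (r - 1)

    a_sum = b_sum = c_sum = 0.0
    het = calls[:, 0] != calls[:, 1]
    for allele in alleles:
        cnt = (calls == allele).sum(axis=1)  # 0, 1 or 2 copies
        p_i = np.bincount(g, weights=cnt, minlength=r) / (2.0 * n_i)
        # observed heterozygote proportion carrying this allele
        h_i = np.bincount(g, weights=(het & (cnt == 1)), minlength=r) / n_i
        pbar = (n_i * p_i).sum() / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / nsum

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def wc_theta_locus(
    dataset: GenotypeDataset, locus: str, pops: Sequence[str] | None = None
) -> tuple[float, float, float]:
    """Weir–Cockerham variance components (a, b, c) for one locus.

    Components are summed over alleles; a monomorphic locus returns
    ``(0, 0, 0)``. ``pops`` restricts the computation to a subset of
    populations.
    """
    ds = dataset if pops is None else dataset.subset_populations(pops)
    try:
        li = ds.loci.index(locus)
    except ValueError:
        raise KeyError(f"unknown locus {locus!r}") from None
    calls = ds.calls[:, li, :]
    present = calls[calls[:, 0] != MISSING]
    if present.size and np.unique(present).size == 1:
        return (0.0, 0.0, 0.0)
    return _locus_components(calls, ds.pop_index, ds.n_populations)


def _all_components(ds: GenotypeDataset) -> np.ndarray:
    """(n_loci, 3) array of summed components, zeros for monomorphic loci."""
    comps = np.zeros((len(ds.loci), 3))
    for li, locus in enumerate(ds.loci):
        comps[li] = wc_theta_locus(ds, locus)
    return comps


def _theta_from_components(comps: np.ndarray) -> float:
    num = comps[:, 0].sum()
    den = comps.sum()
    if den == 0.0:
        raise NoVariationError("no allelic variation: theta undefined")
    return float(num / den)


def multilocus_theta(dataset: GenotypeDataset, pops: Sequence[str] | None = None) -> float:
    """Multilocus Weir–Cockerham theta, the ratio-of-sums estimator.

    theta = sum_l a_l / sum_l (a_l + b_l + c_l). Loci with zero total
    variance contribute nothing; negative estimates are reported as
    computed.
    """
    ds = dataset if pops is None else dataset.subset_populations(pops)
    if ds.n_populations < 2:
        raise ValueError("theta needs >= 2 populations")
    return _theta_from_components(_all_components(ds))


def pairwise_fst(dataset: GenotypeDataset) -> pd.DataFrame:
    """Symmetric matrix of pairwise multilocus theta (diagonal zero).

    Pairs with no informative locus are NaN.
    """
    pops = dataset.populations
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            try:
                theta = multilocus_theta(dataset, pops=[pops[i], pops[j]])
            except NoVariationError:
                theta = np.nan
            mat.iloc[i, j] = mat.iloc[j, i] = theta
    return mat


def bootstrap_fst_ci(
    dataset: GenotypeDataset,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for multilocus theta, resampling loci.

    Replicates whose resampled loci carry no variation are discarded (and
    counted); an error is raised if every replicate degenerates.
    """
    if len(dataset.loci) < 2:
        raise ValueError("bootstrap over loci needs >= 2 loci")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    comps = _all_components(dataset)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(dataset.loci), size=(n_boot, len(dataset.loci)))
    num = comps[idx, 0].sum(axis=1)
    den = comps[idx, :].sum(axis=(1, 2))
    good = den != 0.0
    if not good.any():
        raise NoVariationError("every bootstrap replicate was degenerate")
    thetas = num[good] / den[good]
    lo, hi = np.percentile(thetas, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def jackknife_fst_ci(dataset: GenotypeDataset, alpha: float = 0.05) -> tuple[float, float]:
    """Delete-one-locus jackknife normal-theory CI for multilocus theta."""
    comps = _all_components(dataset)
    L = comps.shape[0]
    if L < 2:
        raise ValueError("jackknife needs >= 2 loci")
    theta_hat = _theta_from_components(comps)
    loo = np.empty(L)
    for l in range(L):
        loo[l] = _theta_from_components(np.delete(comps, l, axis=0))
    pseudo = L * theta_hat - (L - 1) * loo
    se = pseudo.std(ddof=1) / np.sqrt(L)
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    return float(theta_hat - z * se), float(theta_hat + z * se)


@dataclass
class FstResult:
    """Multilocus F_ST estimate with per-locus detail and a resampled CI."""

    theta_global: float
    theta_per_locus: dict[str, float]
    ci_low: float
    ci_high: float
    pairwise: pd.DataFrame
    n_boot: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "theta_global": self.theta_global,
            "theta_per_locus": self.theta_per_locus,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "populations": list(self.pairwise.index),
            "pairwise": self.pairwise.to_numpy().tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @staticmethod
    def from_json(path: str | Path) -> "FstResult":
        d = json.loads(Path(path).read_text())
        pairwise = pd.DataFrame(
            np.array(d["pairwise"]), index=d["populations"], columns=d["populations"]
        )
        return FstResult(
            theta_global=d["theta_global"],
            theta_per_locus=d["theta_per_locus"],
            ci_low=d["ci_low"],
            ci_high=d["ci_high"],
            pairwise=pairwise,
            n_boot=d["n_boot"],
            seed=d["seed"],
        )

    def per_locus_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"locus": list(self.theta_per_locus), "theta": list(self.theta_per_locus.values())}
        )


def fst_analysis(dataset: GenotypeDataset, n_boot: int = 10_000, seed: int = 0) -> FstResult:
    """Global + per-locus + pairwise theta with a bootstrap CI over loci."""
    per_locus: dict[str, float] = {}
    for locus in dataset.loci:
        a, b, c = wc_theta_locus(dataset, locus)
        tot = a + b + c
        per_locus[locus] = float(a / tot) if tot else np.nan
    ci_low, ci_high = bootstrap_fst_ci(dataset, n_boot=n_boot, seed=seed)
    return FstResult(
        theta_global=multilocus_theta(dataset),
        theta_per_locus=per_locus,
        ci_low=ci_low,
        ci_high=ci_high,
        pairwise=pairwise_fst(dataset),
        n_boot=n_boot,
        seed=seed,
    )
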