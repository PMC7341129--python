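"""uSFS dataset container, text I/O, bootstraps and summary statistics.

A dataset pairs the unfolded SFS of a selected class (nonsynonymous sites)
with that of a neutral comparator (synonymous sites), optionally with
per-class substitution counts against an outgroup.  Only the 2n-1
polymorphic frequency classes are stored; derived alleles fixed in the
sample are accounted with divergence (see the expectation/sampling code in
``prf_core``), keeping the polymorphism/divergence split explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "USFSDataset",
    "SummaryStats",
    "pi_from_sfs",
    "alpha_obs",
    "seg_adv_fraction",
    "summarize_replicates",
    "bootstrap_datasets",
    "read_usfs",
    "write_usfs",
    "write_polydfe",
]


@dataclass
class USFSDataset:
    """Paired neutral/selected uSFS counts with optional divergence.

    ``neutral_sfs`` and ``selected_sfs`` hold counts for derived-allele
    frequencies ``1 .. 2n-1`` in ``n_chrom = 2n`` sampled genome copies;
    ``L_neut``/``L_sel`` are the numbers of sites behind each class.
    Divergence counts must be present for both classes or neither.
    """

    neutral_sfs: np.ndarray
    selected_sfs: np.ndarray
    L_neut: float
    L_sel: float
    n_chrom: int
    div_neut: Optional[int] = None
    div_sel: Optional[int] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.neutral_sfs = np.asarray(self.neutral_sfs, dtype=np.int64)
        self.selected_sfs = np.asarray(self.selected_sfs, dtype=np.int64)
        if self.neutral_sfs.shape != self.selected_sfs.shape:
            raise ValueError("neutral and selected uSFS vectors differ in length")
        if self.neutral_sfs.ndim != 1 or self.neutral_sfs.size != self.n_chrom - 1:
            raise ValueError(
                f"uSFS vectors must have length n_chrom - 1 = {self.n_chrom - 1}, "
                f"got {self.neutral_sfs.size}"
            )
        if np.any(self.neutral_sfs < 0) or np.any(self.selected_sfs < 0):
            raise ValueError("uSFS counts must be non-negative")
        if (self.div_neut is None) != (self.div_sel is None):
            raise ValueError("divergence counts must be present for both classes or neither")
        if self.L_neut <= 0 or self.L_sel <= 0:
            raise ValueError("site counts L_neut and L_sel must be positive")

    @property
    def has_divergence(self) -> bool:
        return self.div_neut is not None


@dataclass
class SummaryStats:
    """Population-genetic summaries of a simulated dataset."""

    pi_s: float
    pi_ratio: float          # pi_S / pi_0
    alpha_obs: Optional[float]
    s_adv: int
    s_total: int
    s_adv_fraction: float

    def __post_init__(self) -> None:
        if self.alpha_obs is not None and not (0.0 <= self.alpha_obs <= 1.0):
            raise ValueError("alpha_obs must lie in [0, 1]")
        if not (0.0 <= self.s_adv_fraction <= 1.0):
            raise ValueError("s_adv_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def pi_from_sfs(sfs: Sequence[float], L: float, n_chrom: int) -> float:
    """Pairwise nucleotide diversity per site from an (u)SFS.

    ``pi = sum_i 2*i*(2n-i)*sfs_i / (2n*(2n-1)) / L`` — the mean fraction of
    sites at which two sampled genome copies differ.
    """
    if L <= 0:
        raise ValueError("site count L must be positive")
    sfs = np.asarray(sfs, dtype=float)
    i = np.arange(1, sfs.size + 1)
    num = np.sum(2.0 * i * (n_chrom - i) * sfs)
    return float(num / (n_chrom * (n_chrom - 1)) / L)


def _gamma_of(item) -> float:
    if hasattr(item, "gamma"):
        return item.gamma
    return item[1]


def _class_of(item) -> str:
    if hasattr(item, "site_class"):
        return item.site_class
    return item[0]


def alpha_obs(substitutions: Iterable) -> Optional[float]:
    """Observed proportion of adaptive substitutions.

    ``alpha_Obs = dN_a / (dN_a + dN_d)``: the fraction of nonsynonymous
    substitutions whose recorded scaled effect is positive.  Returns ``None``
    (undefined) when no nonsynonymous substitution is present.
    """
    n_adv = n_tot = 0
    for s in substitutions:
        if _class_of(s) != "nonsyn":
            continue
        n_tot += 1
        if _gamma_of(s) > 0:
            n_adv += 1
    if n_tot == 0:
        return None
    return n_adv / n_tot


def seg_adv_fraction(variants: Iterable) -> float:
    """Fraction of segregating nonsynonymous variants that are beneficial.

    ``S_Adv / S``, with the convention 0 when nothing segregates.
    """
    n_adv = n_tot = 0
    for v in variants:
        if _class_of(v) != "nonsyn":
            continue
        n_tot += 1
        if _gamma_of(v) > 0:
            n_adv += 1
    if n_tot == 0:
        return 0.0
    return n_adv / n_tot


def summarize_replicates(replicates: Sequence, pi0: float = 0.01) -> SummaryStats:
    """Pool forward replicates into the standard summary statistics.

    Synonymous diversity ``pi_S`` is computed from the pooled sample uSFS of
    exonic synonymous sites and expressed relative to the configured neutral
    expectation ``pi0`` (default ``4*N_e*mu = 0.01``).
    """
    from .wf_forward import sample_usfs_from_replicates  # local: avoids cycle

    ds = sample_usfs_from_replicates(replicates)
    pi_s = pi_from_sfs(ds.neutral_sfs, ds.L_neut, ds.n_chrom)
    subs = [s for rep in replicates for s in rep.substitutions]
    variants = [v for rep in replicates for v in rep.variants]
    nonsyn = [v for v in variants if v.site_class == "nonsyn"]
    s_adv = sum(1 for v in nonsyn if v.gamma > 0)
    return SummaryStats(
        pi_s=pi_s,
        pi_ratio=pi_s / pi0,
        alpha_obs=alpha_obs(subs),
        s_adv=s_adv,
        s_total=len(nonsyn),
        s_adv_fraction=seg_adv_fraction(variants),
    )


def bootstrap_datasets(replicates: Sequence, B: int = 100,
                       seed: Optional[int] = None) -> list:
    """Bootstrap forward replicates into ``B`` pooled uSFS datasets.

    Each bootstrap draws replicates with replacement up to the original
    count and pools them; deterministic given ``seed``.
    """
    from .wf_forward import sample_usfs_from_replicates  # local: avoids cycle

    if B < 1:
        raise ValueError("B must be >= 1")
    if len(replicates) == 0:
        raise ValueError("cannot bootstrap an empty replicate list")
    rng = np.random.default_rng(seed)
    out = []
    n = len(replicates)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        ds = sample_usfs_from_replicates([replicates[i] for i in idx])
        ds.provenance = dict(ds.provenance, bootstrap=b, seed=seed)
        out.append(ds)
    return out


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------


def _fmt_L(L: float) -> str:
    return str(int(L)) if float(L).is_integer() else repr(float(L))


def write_usfs(path, dataset: USFSDataset) -> None:
    """Write a dataset in the whitespace-delimited uSFS text format.

    Layout: '#' comment lines; header ``n_chrom L_neut L_sel div_flag``;
    one line of 2n-1 neutral counts; one line of 2n-1 selected counts; and,
    when divergence is present, a final line ``div_neut div_sel``.
    """
    with open(path, "w") as fh:
        for key, val in dataset.provenance.items():
            fh.write(f"# {key}: {val}\n")
        flag = 1 if dataset.has_divergence else 0
        fh.write(f"{dataset.n_chrom} {_fmt_L(dataset.L_neut)} {_fmt_L(dataset.L_sel)} {flag}\n")
        fh.write(" ".join(str(int(c)) for c in dataset.neutral_sfs) + "\n")
        fh.write(" ".join(str(int(c)) for c in dataset.selected_sfs) + "\n")
        if dataset.has_divergence:
            fh.write(f"{int(dataset.div_neut)} {int(dataset.div_sel)}\n")


class USFSParseError(ValueError):
    pass


def read_usfs(path) -> USFSDataset:
    """Read a dataset written by :func:`write_usfs`.

    Malformed content raises :class:`USFSParseError` naming the line.
    """
    lines = []
    provenance = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    provenance[k.strip()] = v.strip()
                continue
            lines.append((lineno, line))
    if len(lines) < 3:
        raise USFSParseError(f"{path}: expected at least 3 data lines, found {len(lines)}")

    lineno, header = lines[0]
    fields = header.split()
    if len(fields) not in (3, 4):
        raise USFSParseError(f"{path}:{lineno}: header must be 'n_chrom L_neut L_sel [div_flag]'")
    try:
        n_chrom = int(fields[0])
        L_neut = float(fields[1])
        L_sel = float(fields[2])
        div_flag = int(fields[3]) if len(fields) == 4 else 0
    except ValueError as exc:
        raise USFSParseError(f"{path}:{lineno}: non-numeric header field ({exc})") from None

    def parse_counts(entry, label):
        ln, text = entry
        try:
            vec = np.array([int(tok) for tok in text.split()], dtype=np.int64)
        except ValueError:
            raise USFSParseError(f"{path}:{ln}: non-integer count in {label} uSFS") from None
        if vec.size != n_chrom - 1:
            raise USFSParseError(
                f"{path}:{ln}: {label} uSFS has {vec.size} entries, header implies {n_chrom - 1}"
            )
        return vec

    neutral = parse_counts(lines[1], "neutral")
    selected = parse_counts(lines[2], "selected")

    div_neut = div_sel = None
    if div_flag:
        if len(lines) < 4:
            raise USFSParseError(f"{path}: divergence flagged in header but no divergence line")
        ln, text = lines[3]
        toks = text.split()
        if len(toks) != 2:
            raise USFSParseError(
                f"{path}:{ln}: divergence line must hold exactly two counts (neutral, selected)"
            )
        div_neut, div_sel = int(toks[0]), int(toks[1])
        extra = lines[4:]
    else:
        extra = lines[3:]
    if extra:
        raise USFSParseError(f"{path}:{extra[0][0]}: unexpected trailing data line")
    return USFSDataset(
        neutral_sfs=neutral, selected_sfs=selected, L_neut=L_neut, L_sel=L_sel,
        n_chrom=n_chrom, div_neut=div_neut, div_sel=div_sel, provenance=provenance,
    )


def write_polydfe(path, dataset: USFSDataset) -> None:
    """Emit the polyDFE v2.0 input dialect for cross-validation.

    One neutral and one selected fragment; each fragment line lists the
    2n-1 polymorphism counts followed by the site count, and, when present,
    the substitution count with its site count.  Best-effort dialect for
    interoperability; the package's own round-trip format is
    :func:`write_usfs`.
    """
    with open(path, "w") as fh:
        fh.write(f"1 1 {dataset.n_chrom}\n")
        for sfs, L, div in (
            (dataset.neutral_sfs, dataset.L_neut, dataset.div_neut),
            (dataset.selected_sfs, dataset.L_sel, dataset.div_sel),
        ):
            toks = [str(int(c)) for c in sfs] + [_fmt_L(L)]
            if div is not None:
                toks += [str(int(div)), _fmt_L(L)]
            fh.write(" ".join(toks) + "\n")
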