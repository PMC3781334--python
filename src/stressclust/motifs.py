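"""Single-site transcription-factor binding-site over-representation.

Promoter windows of +/-2000 bp around each TSS are scanned on both strands
with JASPAR-style position weight matrices.  A position is a hit when its
relative log-odds score — (score - min) / (max - min) — reaches the
threshold (0.85 by default, the conventional single-site setting).  Per
factor, over-representation of hits in a target gene set against a
background set is summarized two ways, mirroring single-site analysis
practice:

* a Z-score on site counts under a binomial background-rate model with
  continuity correction: r = background hits / background scanned
  positions, mu = r * target scanned positions, sigma = sqrt(mu (1 - r)),
  Z = (x - mu - 0.5) / sigma;
* a one-tailed Fisher exact test on the 2x2 table of genes with >= 1 hit
  versus without, target versus rest-of-background.

Factors passing both Z > 10 and Fisher p < 0.01 (the published cutoffs) are
flagged, and a regulator -> target edge list restricted to an annotation
subset can be exported for network tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParseError, StressclustError

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N

DEFAULT_WINDOW = 2000
DEFAULT_REL_THRESHOLD = 0.85
DEFAULT_PSEUDOCOUNT = 0.8
Z_MIN = 10.0
FISHER_MAX = 0.01

UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass
class PWM:
    """A position frequency matrix and its log-odds scoring machinery.

    ``counts`` has shape (4, width), rows in A, C, G, T order.  The total
    pseudocount is split across the four bases in proportion to the
    background frequencies before the log-odds transform.
    """

    name: str
    counts: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise StressclustError(f"PWM {self.name}: counts must be 4 x width")
        if (self.counts < 0).any():
            raise StressclustError(f"PWM {self.name}: negative counts")
        if (self.counts.sum(axis=0) == 0).any():
            raise StressclustError(f"PWM {self.name}: all-zero column")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def log_odds(self, background: np.ndarray = UNIFORM_BACKGROUND) -> np.ndarray:
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()
        adj = self.counts + self.pseudocount * bg[:, None]
        probs = adj / adj.sum(axis=0, keepdims=True)
        return np.log2(probs / bg[:, None])

    def score_range(self, background: np.ndarray = UNIFORM_BACKGROUND):
        lom = self.log_odds(background)
        lo, hi = lom.min(axis=0).sum(), lom.max(axis=0).sum()
        if not hi > lo:
            raise StressclustError(f"PWM {self.name}: degenerate score range")
        return lo, hi

    def probabilities(self) -> np.ndarray:
        """Per-position base distribution (no pseudocount) for site sampling."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


def write_jaspar_pfm(pwms: list[PWM], path) -> None:
    """Write PWMs in JASPAR PFM text format (``>ID name`` + bracketed rows)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name} {pwm.name}\n")
            for base, row in zip(BASES, pwm.counts):
                fh.write(f"{base} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")
    logger.info("wrote %d PWMs to %s", len(pwms), path)


def read_jaspar_pfm(path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """Parse a JASPAR PFM text file into PWMs.

    Accepts both the bracketed dialect (``A [ 1 2 3 ]``) and bare
    whitespace-separated count rows; four rows per record in A, C, G, T
    order.  Malformed rows raise :class:`ParseError` with the line number.
    """
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []

    def flush(lineno):
        nonlocal name, rows
        if name is None:
            return
        if len(rows) != 4:
            raise ParseError(f"{path}:{lineno}: matrix {name!r} has {len(rows)} "
                             "count rows, expected 4")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ParseError(f"{path}:{lineno}: matrix {name!r} has unequal row lengths")
        pwms.append(PWM(name, np.array(rows), pseudocount=pseudocount))
        name, rows = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                name = line[1:].split()[0] if line[1:].split() else None
                if not name:
                    raise ParseError(f"{path}:{lineno}: empty matrix header")
                continue
            if name is None:
                raise ParseError(f"{path}:{lineno}: count row before any '>' header")
            body = line
            if body[0].upper() in BASES and not body[0].isdigit():
                expected = BASES[len(rows)] if len(rows) < 4 else "?"
                if body[0].upper() != expected:
                    raise ParseError(f"{path}:{lineno}: expected row for base "
                                     f"{expected}, found {body[0]!r}")
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            try:
                rows.append([float(tok) for tok in body.split()])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric count ({exc})") from exc
    flush(lineno if name else 0)
    if not pwms:
        raise ParseError(f"{path}: no matrices found")
    return pwms


def encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes (A=0..T=3, anything else 4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.size, 4, dtype=np.int8)
    for base, i in _CODE.items():
        codes[arr == ord(base)] = i
    return codes


def estimate_background(promoters: dict[str, str]) -> np.ndarray:
    """Base frequencies of the supplied promoter set (non-ACGT ignored)."""
    counts = np.zeros(4)
    for seq in promoters.values():
        codes = encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        raise StressclustError("cannot estimate background from empty sequences")
    return counts / counts.sum()


def _window_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Score every start position; windows through non-ACGT score -inf."""
    w = lom.shape[1]
    lom5 = np.vstack([lom, np.full((1, w), -np.inf)])
    if codes.size < w:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return lom5[windows, np.arange(w)].sum(axis=1)


@dataclass
class ScanResult:
    """Hits plus per-gene scanned-position accounting for one PWM set."""

    hits: pd.DataFrame  # gene, factor, position, strand, rel_score
    scanned: pd.DataFrame  # gene, factor, n_positions
    rel_threshold: float
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())


def scan_promoters(pwms, promoters: dict[str, str], tss: dict[str, int],
                   window: int = DEFAULT_WINDOW,
                   rel_threshold: float = DEFAULT_REL_THRESHOLD,
                   background="estimate") -> ScanResult:
    """Scan both strands of each promoter window with each PWM.

    ``promoters`` maps gene id to its (strand-oriented) sequence and ``tss``
    gives the 0-based index of the TSS base within that sequence.  Positions
    in hits are TSS-relative site starts (negative = upstream).  Sequences
    shorter than the full +/-window are scanned over their available span
    with a warning.  Where both strands hit the same start position, only
    the higher-scoring strand is reported (ties go to '+').
    """
    if isinstance(pwms, PWM):
        pwms = [pwms]
    if not 0.0 < rel_threshold <= 1.0:
        raise StressclustError("rel_threshold must be in (0, 1]")
    if isinstance(background, str) and background == "estimate":
        bg = estimate_background(promoters)
    else:
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()

    hit_rows, scan_rows = [], []
    for pwm in pwms:
        lom = pwm.log_odds(bg)
        lo, hi = pwm.score_range(bg)
        w = pwm.width
        rc_lom = lom[::-1, ::-1]  # complement rows, reverse columns
        for gene, seq in promoters.items():
            if gene not in tss:
                raise StressclustError(f"gene {gene!r} missing from TSS table")
            center = tss[gene]
            start = max(0, center - window)
            stop = min(len(seq), center + window + 1)
            if stop - start < 2 * window + 1:
                logger.warning("gene %s: sequence covers only [%d, %d) of the "
                               "+/-%d bp window", gene, start - center,
                               stop - center, window)
            codes = encode(seq[start:stop])
            fwd = _window_scores(codes, lom)
            rev = _window_scores(codes, rc_lom)
            n_pos = fwd.size
            scan_rows.append((gene, pwm.name, n_pos))
            if n_pos == 0:
                continue
            with np.errstate(invalid="ignore"):
                rel_f = (fwd - lo) / (hi - lo)
                rel_r = (rev - lo) / (hi - lo)
            best = np.where(rel_f >= rel_r, rel_f, rel_r)
            strands = np.where(rel_f >= rel_r, "+", "-")
            idx = np.nonzero(best >= rel_threshold)[0]
            for i in idx:
                hit_rows.append((gene, pwm.name, int(start + i - center),
                                 strands[i], float(best[i])))
    hits = pd.DataFrame(hit_rows,
                        columns=["gene", "factor", "position", "strand", "rel_score"])
    scanned = pd.DataFrame(scan_rows, columns=["gene", "factor", "n_positions"])
    logger.info("scan: %d hits over %d gene x factor windows", len(hits), len(scanned))
    return ScanResult(hits, scanned, rel_threshold, bg)


def single_site_analysis(scan: ScanResult, target_genes, background_genes,
                         z_min: float = Z_MIN,
                         fisher_max: float = FISHER_MAX) -> pd.DataFrame:
    """Per-factor site-count Z-score and gene-level Fisher exact test.

    ``target_genes`` must be a subset of ``background_genes``; the Fisher
    table contrasts target genes against the remaining background genes.
    Returns one row per factor with the pass flag Z > z_min and
    p < fisher_max.  A zero-sigma factor reports a null Z with a reason.
    """
    target = set(target_genes)
    background = set(background_genes)
    if not background:
        raise StressclustError("empty background gene set")
    if not target <= background:
        raise StressclustError("target genes must be a subset of the background")

    hits = scan.hits[scan.hits["gene"].isin(background)]
    scanned = scan.scanned[scan.scanned["gene"].isin(background)]
    rows = []
    for factor, sub in scanned.groupby("factor"):
        pos_by_gene = sub.set_index("gene")["n_positions"]
        bg_positions = int(pos_by_gene.sum())
        tg_positions = int(pos_by_gene[pos_by_gene.index.isin(target)].sum())
        fhits = hits[hits["factor"] == factor]
        x = int(fhits["gene"].isin(target).sum())
        bg_hits = len(fhits)
        r = bg_hits / bg_positions if bg_positions else 0.0
        mu = r * tg_positions
        sigma = np.sqrt(mu * (1.0 - r))
        if sigma > 0:
            z = (x - mu - 0.5) / sigma
            z_reason = ""
        else:
            z = np.nan
            z_reason = "zero background hit rate" if r == 0 else "degenerate variance"
        genes_hit = set(fhits["gene"])
        t_hit = len(genes_hit & target)
        t_miss = len(target) - t_hit
        rest = background - target
        r_hit = len(genes_hit & rest)
        r_miss = len(rest) - r_hit
        _, fisher_p = stats.fisher_exact([[t_hit, t_miss], [r_hit, r_miss]],
                                         alternative="greater")
        rows.append({"factor": factor, "x": x, "background_hits": bg_hits,
                     "background_rate": r, "mu": mu, "z": z, "z_reason": z_reason,
                     "target_genes_hit": t_hit,
                     "background_genes_hit": r_hit + t_hit,
                     "fisher_p": float(fisher_p),
                     "passes": bool(np.isfinite(z) and z > z_min
                                    and fisher_p < fisher_max)})
    return pd.DataFrame(rows).sort_values("factor").reset_index(drop=True)


def export_regulator_network(results: pd.DataFrame, scan: ScanResult,
                             subset_genes, confirmed_sites: pd.DataFrame | None = None
                             ) -> pd.DataFrame:
    """Edge list (factor, gene, evidence) for factors passing the thresholds.

    Edges connect each passing factor to the subset genes in which it has at
    least one predicted site; genes listed in ``confirmed_sites`` (columns
    factor, gene) for that factor are labeled ``confirmed`` instead of
    ``predicted``.
    """
    subset = set(subset_genes)
    confirmed = set()
    if confirmed_sites is not None and len(confirmed_sites):
        confirmed = set(zip(confirmed_sites["factor"], confirmed_sites["gene"]))
    edges = []
    for factor in results.loc[results["passes"], "factor"]:
        fhits = scan.hits[(scan.hits["factor"] == factor)
                          & scan.hits["gene"].isin(subset)]
        for gene in sorted(set(fhits["gene"])):
            evidence = "confirmed" if (factor, gene) in confirmed else "predicted"
            edges.append({"factor": factor, "gene": gene, "evidence": evidence})
    return pd.DataFrame(edges, columns=["factor", "gene", "evidence"])


def read_tss_bed(path) -> pd.DataFrame:
    """Read a BED (0-based half-open) TSS table: chrom start end name score strand."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append({"chrom": parts[0], "start": start, "end": end,
                         "name": parts[3], "strand": strand})
    return pd.DataFrame(rows)
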