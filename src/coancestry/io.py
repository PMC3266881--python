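"""Readers and writers for haplotype panels, genetic maps, coancestry matrices
and MCMC traces.

All on-disk artifacts are plain text.  A panel file holds one chromosome; a
multi-chromosome analysis is a list of ``(HaplotypePanel, GeneticMap)`` pairs
whose painting results are summed downstream.

Haplotype dialects
------------------
``phase``
    The package's own documented dialect::

        <n_haps>
        <n_sites>
        P <pos_1> ... <pos_L>
        010010...          (one row of 0/1 characters per haplotype)

``impute``
    IMPUTE2-style ``.hap`` (one row per site, space-separated 0/1 columns,
    one column per haplotype) plus ``.legend`` (header line, then
    ``id position a0 a1`` rows).

``matrix``
    Bare rows of 0/1 characters, one per haplotype; positions default to
    ``1..L``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypePanel",
    "GeneticMap",
    "read_haplotypes",
    "write_haplotypes",
    "read_map",
    "write_map",
    "read_coancestry",
    "write_coancestry",
    "read_trace_records",
    "write_trace_records",
]

CM_PER_MB_TO_MORGANS_PER_BP = 1e-8


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes for one chromosome.

    Parameters
    ----------
    alleles
        ``(H, L)`` matrix of 0/1 alleles, one row per haplotype.
    positions
        Strictly increasing 1-based base-pair coordinate per site.
    chrom
        Chromosome identifier for every site in the panel.
    hap_to_ind
        Haplotype index -> individual index.  Every individual owns exactly
        two haplotypes (diploid) or one (haploid); consecutive by default.
    labels
        Optional sample-label string per individual.
    """

    alleles: np.ndarray
    positions: np.ndarray
    chrom: str = "1"
    hap_to_ind: np.ndarray | None = None
    labels: list[str] | None = None
    ploidy: int = field(init=False)

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (haplotypes x sites) matrix")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1")
        H = self.alleles.shape[0]
        if H < 4:
            raise ValueError(f"need at least 4 haplotypes, got {H}")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape != (self.alleles.shape[1],):
            raise ValueError("positions length must match the number of sites")
        if self.n_sites > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        if self.hap_to_ind is None:
            # default pairing: haplotypes 2i, 2i+1 belong to individual i
            if H % 2:
                raise ValueError("odd haplotype count requires explicit hap_to_ind")
            self.hap_to_ind = np.repeat(np.arange(H // 2), 2)
        self.hap_to_ind = np.asarray(self.hap_to_ind, dtype=np.int64)
        if self.hap_to_ind.shape != (H,):
            raise ValueError("hap_to_ind length must equal the haplotype count")
        counts = np.bincount(self.hap_to_ind)
        if counts.min() < 1 or len(set(counts.tolist())) != 1 or counts.max() > 2:
            raise ValueError("every individual must own exactly 1 or 2 haplotypes")
        self.ploidy = int(counts[0])
        if self.labels is not None and len(self.labels) != self.n_ind:
            raise ValueError("labels length must equal the individual count")

    @property
    def n_haps(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_ind(self) -> int:
        return int(self.hap_to_ind.max()) + 1

    def haps_of(self, ind: int) -> np.ndarray:
        return np.flatnonzero(self.hap_to_ind == ind)

    def genotypes(self) -> np.ndarray:
        """Per-individual allele-1 dosage matrix, shape ``(n_ind, L)``."""
        out = np.zeros((self.n_ind, self.n_sites), dtype=np.int16)
        np.add.at(out, self.hap_to_ind, self.alleles)
        return out

    def restrict_sites(self, mask: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(
            self.alleles[:, mask],
            self.positions[mask],
            chrom=self.chrom,
            hap_to_ind=self.hap_to_ind,
            labels=self.labels,
        )

    def singleton_mask(self) -> np.ndarray:
        """True for sites whose minor allele is carried by >1 individual.

        Sites varying in only a single individual carry no donor information
        (the only matching haplotypes are excluded as donors) and are dropped
        before unlinked painting.
        """
        geno = self.genotypes()
        carriers1 = (geno > 0).sum(axis=0)
        carriers0 = (geno < self.ploidy).sum(axis=0)
        return (carriers1 > 1) & (carriers0 > 1)


@dataclass
class GeneticMap:
    """Recombination map: base-pair positions and local rate in cM/Mb.

    Genetic distance between two coordinates is the trapezoidal integral of
    the rate column; coordinates outside the mapped range extend the edge
    rate.  ``None`` maps downstream fall back to :meth:`uniform`.
    """

    positions: np.ndarray
    rates_cm_per_mb: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.rates_cm_per_mb = np.asarray(self.rates_cm_per_mb, dtype=np.float64)
        if self.positions.ndim != 1 or self.positions.size == 0:
            raise ParseError("genetic map must contain at least one row")
        if self.positions.size > 1 and not (np.diff(self.positions) > 0).all():
            raise ParseError("genetic map positions must be strictly increasing")
        if (self.rates_cm_per_mb < 0).any():
            raise ParseError("recombination rates must be non-negative")

    @classmethod
    def uniform(cls, rate_cm_per_mb: float = 1.0) -> "GeneticMap":
        return cls(np.array([1.0]), np.array([float(rate_cm_per_mb)]))

    def cumulative_morgans(self, bp: np.ndarray) -> np.ndarray:
        """Cumulative genetic position (Morgans) at base-pair coordinates."""
        bp = np.atleast_1d(np.asarray(bp, dtype=np.float64))
        pos, rate = self.positions, self.rates_cm_per_mb
        if pos.size == 1:
            return bp * rate[0] * CM_PER_MB_TO_MORGANS_PER_BP
        # trapezoidal cumulative integral of the piecewise-linear rate,
        # constant-extended beyond both map edges; cM/Mb * bp = 1e-8 Morgans
        seg = np.diff(pos) * (rate[:-1] + rate[1:]) / 2.0
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        inner = np.interp(bp, pos, cum)
        left = bp < pos[0]
        right = bp > pos[-1]
        inner[left] = (bp[left] - pos[0]) * rate[0]
        inner[right] = cum[-1] + (bp[right] - pos[-1]) * rate[-1]
        return inner * CM_PER_MB_TO_MORGANS_PER_BP

    def intersite_morgans(self, bp_positions: np.ndarray) -> np.ndarray:
        """Genetic distance (Morgans) between successive panel sites."""
        cum = self.cumulative_morgans(np.asarray(bp_positions, dtype=np.float64))
        return np.maximum(np.diff(cum), 0.0)


def read_haplotypes(
    path: str | Path,
    format: str = "phase",
    positions: np.ndarray | None = None,
    legend_path: str | Path | None = None,
    chrom: str = "1",
    ploidy: int = 2,
    on_bad_sites: str = "error",
) -> HaplotypePanel:
    """Read a phased haplotype panel.

    ``on_bad_sites`` controls sites containing characters other than 0/1
    (missing data): ``"error"`` rejects the file, ``"drop"`` removes the
    sites.
    """
    path = Path(path)
    if format == "phase":
        lines = path.read_text().splitlines()
        if len(lines) < 4:
            raise ParseError(f"{path}: truncated phase file")
        try:
            n_haps = int(lines[0].split()[0])
            n_sites = int(lines[1].split()[0])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: bad header: {exc}") from None
        ptoks = lines[2].split()
        if ptoks[0] != "P" or len(ptoks) != n_sites + 1:
            raise ParseError(f"{path}: line 3 must be 'P <positions...>'")
        positions = np.array([int(t) for t in ptoks[1:]], dtype=np.int64)
        rows = lines[3 : 3 + n_haps]
        if len(rows) < n_haps:
            raise ParseError(f"{path}: expected {n_haps} haplotype rows")
        alleles, keep = _parse_rows(rows, n_sites, path, on_bad_sites, offset=4)
        positions = positions[keep]
    elif format == "matrix":
        rows = [ln for ln in path.read_text().splitlines() if ln.strip()]
        if not rows:
            raise ParseError(f"{path}: empty file")
        L = len(rows[0].strip())
        alleles, keep = _parse_rows(rows, L, path, on_bad_sites, offset=1)
        if positions is None:
            positions = np.arange(1, L + 1, dtype=np.int64)
        positions = np.asarray(positions, dtype=np.int64)[keep]
    elif format == "impute":
        legend_path = Path(legend_path) if legend_path else path.with_suffix(".legend")
        leg = pd.read_csv(legend_path, sep=r"\s+")
        if "position" not in leg.columns:
            raise ParseError(f"{legend_path}: legend needs a 'position' column")
        positions = leg["position"].to_numpy(dtype=np.int64)
        site_rows = np.loadtxt(path, dtype=np.int64, ndmin=2)
        if site_rows.shape[0] != positions.size:
            raise ParseError(
                f"{path}: {site_rows.shape[0]} sites but legend has {positions.size}"
            )
        alleles = site_rows.T
        if not np.isin(alleles, (0, 1)).all():
            if on_bad_sites == "drop":
                good = np.isin(alleles, (0, 1)).all(axis=0)
                alleles, positions = alleles[:, good], positions[good]
            else:
                raise ParseError(f"{path}: non-biallelic entries")
    else:
        raise ValueError(f"unknown haplotype format {format!r}")
    if alleles.shape[0] < 4:
        raise ValueError(f"{path}: fewer than 4 haplotypes")
    hap_to_ind = None
    if ploidy == 1:
        hap_to_ind = np.arange(alleles.shape[0])
    return HaplotypePanel(alleles, positions, chrom=chrom, hap_to_ind=hap_to_ind)


def _parse_rows(rows, n_sites, path, on_bad_sites, offset):
    mat = []
    for i, row in enumerate(rows):
        row = row.strip().replace(" ", "")
        if len(row) != n_sites:
            raise ParseError(
                f"{path}: line {i + offset}: row length {len(row)} != {n_sites}"
            )
        mat.append([ord(c) - 48 for c in row])
    alleles = np.array(mat, dtype=np.int16)
    ok = np.isin(alleles, (0, 1)).all(axis=0)
    if not ok.all():
        if on_bad_sites == "drop":
            alleles = alleles[:, ok]
        else:
            bad = int(np.flatnonzero(~ok)[0])
            raise ParseError(f"{path}: site {bad + 1} has non-0/1 or missing alleles")
    else:
        ok = np.ones(n_sites, dtype=bool)
    return alleles.astype(np.int8), ok


def write_haplotypes(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel in the package's ``phase`` dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{panel.n_haps}\n{panel.n_sites}\n")
        fh.write("P " + " ".join(str(p) for p in panel.positions) + "\n")
        for row in panel.alleles:
            fh.write("".join("01"[a] for a in row) + "\n")


def read_map(path: str | Path) -> GeneticMap:
    """Read a HapMap-dialect genetic map (tab/space separated).

    The first two numeric columns are position (bp) and rate (cM/Mb); a
    header line is skipped if present.
    """
    path = Path(path)
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        toks = line.replace(",", " ").split()
        if not toks:
            continue
        try:
            rows.append((float(toks[0]), float(toks[1])))
        except (ValueError, IndexError):
            if ln == 1:
                continue  # header
            raise ParseError(f"{path}: line {ln}: expected 'position rate'") from None
    if not rows:
        raise ParseError(f"{path}: empty genetic map")
    arr = np.array(rows)
    return GeneticMap(arr[:, 0], arr[:, 1])


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("position\trate_cM_Mb\n")
        for p, r in zip(gmap.positions, gmap.rates_cm_per_mb):
            fh.write(f"{int(p)}\t{float(r)!r}\n")


def write_coancestry(X: np.ndarray | pd.DataFrame, path: str | Path,
                     ids: list[str] | None = None) -> None:
    """Write a square non-negative zero-diagonal matrix as labelled CSV."""
    if isinstance(X, pd.DataFrame):
        df = X
        M = df.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        if ids is None:
            ids = [f"ind{i}" for i in range(M.shape[0])]
        df = pd.DataFrame(M, index=ids, columns=ids)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("coancestry matrix must be square")
    if (M < 0).any():
        raise ValueError("coancestry matrix must be non-negative")
    if np.abs(np.diag(M)).max(initial=0.0) > 1e-12:
        raise ValueError("coancestry matrix must have a zero diagonal")
    df.to_csv(path, float_format="%.12g")


def read_coancestry(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: coancestry matrix must be square")
    return df


def write_trace_records(records: list[dict], path: str | Path) -> None:
    """Write MCMC trace samples as line-delimited JSON records."""
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_trace_records(path: str | Path) -> list[dict]:
    out = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            out.append(json.loads(line))
    return out
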