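"""Reading, coding and writing of genotype, phenotype and result files.

Genotypes of an F2-type biparental population are recorded per individual and
marker (bin) as one of three symbols: ``A`` (first homozygote), ``H``
(heterozygote) or ``B`` (second homozygote).  The mixed-model machinery works
on two numeric indicator matrices derived from these symbols:

* the additive indicator ``Z`` with +1 for A, 0 for H and -1 for B;
* the dominance indicator ``W`` with 1 for H and 0 for either homozygote.

Users may also supply arbitrary real-valued ``Z``/``W`` tables directly (for
example dosage-like values); in that numeric mode the {+1,0,-1}/{0,1} pairing
is deliberately not enforced, only shape and finiteness.

File dialect: whitespace- or tab-delimited plain text, with an optional header
row auto-detected by a non-numeric first line.  Kinship matrices are written
as gzip-compressed text with a comment header carrying the normalization
constant.  All writers use ``%.17g`` so a write/read round-trip reproduces
every value exactly.
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CodedGenotypes",
    "TraitVector",
    "code_genotypes",
    "decode_genotypes",
    "read_character_genotypes",
    "read_coded_genotypes",
    "read_phenotype",
    "read_covariates",
    "write_kinships",
    "read_kinships",
    "write_variance_components",
    "read_variance_components",
    "write_scan1d",
    "write_scan2d",
    "write_outputs",
]

#: symbol -> (additive indicator, dominance indicator)
GENOTYPE_CODES = {"A": (1.0, 0.0), "H": (0.0, 1.0), "B": (-1.0, 0.0)}

KINSHIP_FILE_NAMES = {
    "a": "km_a.txt.gz",
    "d": "km_d.txt.gz",
    "aa": "km_aa.txt.gz",
    "ad": "km_ad.txt.gz",
    "da": "km_da.txt.gz",
    "dd": "km_dd.txt.gz",
}

VARCOMP_FILE_NAME = "variance_components.txt"
SCAN1D_FILE_NAME = "scan_main.txt"
SCAN2D_FILE_NAME = "scan_epistasis.txt"

_FMT = "%.17g"


@dataclass
class CodedGenotypes:
    """Paired additive/dominance indicator tables with identifiers.

    ``Z`` and ``W`` are n x m arrays (individuals x markers).  When produced
    by :func:`code_genotypes` the entries obey the coding bijection
    (``W == 1`` exactly where ``Z == 0``); user-supplied numeric tables are
    accepted verbatim.
    """

    Z: np.ndarray
    W: np.ndarray
    individual_ids: list[str] = field(default_factory=list)
    marker_ids: list[str] = field(default_factory=list)
    chromosome_of_marker: list[str] | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.Z.ndim != 2 or self.W.ndim != 2:
            raise ValueError("Z and W must be two-dimensional tables")
        if self.Z.shape != self.W.shape:
            raise ValueError(
                f"shape mismatch: Z is {self.Z.shape}, W is {self.W.shape}"
            )
        n, m = self.Z.shape
        if n < 1 or m < 1:
            raise ValueError("need at least one individual and one marker")
        for name, arr in (("Z", self.Z), ("W", self.W)):
            if not np.all(np.isfinite(arr)):
                i, j = np.argwhere(~np.isfinite(arr))[0]
                raise ValueError(
                    f"non-finite value in {name} at row {i + 1}, column {j + 1}"
                )
        if not self.individual_ids:
            self.individual_ids = [f"ind{i + 1:04d}" for i in range(n)]
        if not self.marker_ids:
            self.marker_ids = [f"m{j + 1:04d}" for j in range(m)]
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match n")
        if len(self.marker_ids) != m:
            raise ValueError("marker_ids length does not match m")
        if self.chromosome_of_marker is not None and len(self.chromosome_of_marker) != m:
            raise ValueError("chromosome_of_marker length does not match m")

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def m(self) -> int:
        return self.Z.shape[1]


@dataclass
class TraitVector:
    """A quantitative trait with its fixed-effect design.

    ``y`` holds the n trait values; ``X`` is the n x p fixed-effect design,
    an intercept-only column unless covariates were supplied.  GLS estimates
    of the fixed effects fall out of the REML fit as a by-product.
    """

    y: np.ndarray
    X: np.ndarray | None = None
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.size
        if n < 2:
            raise ValueError("a trait needs at least two individuals")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("phenotype contains non-finite values")
        if self.X is None:
            self.X = np.ones((n, 1))
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.X.shape[0] != n:
            raise ValueError("design matrix rows do not match phenotype length")
        p = self.X.shape[1]
        if p >= n:
            raise ValueError("design matrix has as many columns as observations")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# genotype coding


def code_genotypes(
    raw,
    individual_ids: Sequence[str] | None = None,
    marker_ids: Sequence[str] | None = None,
    chromosome_of_marker: Sequence[str] | None = None,
) -> CodedGenotypes:
    """Numerically code an A/H/B character table into Z and W indicators.

    Any cell outside {A, H, B} (including missing-data symbols) is an error
    naming the offending row and column; no imputation is attempted.
    """
    if isinstance(raw, pd.DataFrame):
        if marker_ids is None:
            marker_ids = [str(c) for c in raw.columns]
        if individual_ids is None:
            individual_ids = [str(i) for i in raw.index]
        raw = raw.to_numpy()
    raw = np.asarray(raw, dtype=object)
    if raw.ndim != 2:
        raise ValueError("genotype table must be two-dimensional")
    n, m = raw.shape
    Z = np.empty((n, m))
    W = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            cell = str(raw[i, j]).strip()
            try:
                Z[i, j], W[i, j] = GENOTYPE_CODES[cell]
            except KeyError:
                raise ValueError(
                    f"invalid genotype symbol {cell!r} at row {i + 1}, "
                    f"column {j + 1}; expected one of A, H, B"
                ) from None
    return CodedGenotypes(
        Z,
        W,
        list(individual_ids) if individual_ids else [],
        list(marker_ids) if marker_ids else [],
        list(chromosome_of_marker) if chromosome_of_marker is not None else None,
    )


def decode_genotypes(g: CodedGenotypes) -> np.ndarray:
    """Invert the coding bijection back to an A/H/B character table."""
    out = np.empty(g.Z.shape, dtype=object)
    for sym, (z, w) in GENOTYPE_CODES.items():
        out[(g.Z == z) & (g.W == w)] = sym
    if (out == None).any():  # noqa: E711 - object array sentinel check
        raise ValueError("table is not in the image of the A/H/B coding")
    return out


# ---------------------------------------------------------------------------
# delimited-table reading


def _sniff_header(path: Path) -> bool:
    """True when the first non-comment, non-blank line is non-numeric."""
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            for tok in line.split():
                try:
                    float(tok)
                except ValueError:
                    return True
            return False
    return False


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_numeric_table(path) -> tuple[np.ndarray, list[str] | None]:
    path = Path(path)
    header = _sniff_header(path)
    df = pd.read_csv(
        path, sep=r"\s+", header=0 if header else None, comment="#",
        float_precision="round_trip",
    )
    cols = [str(c) for c in df.columns] if header else None
    try:
        arr = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.all(np.isfinite(arr)):
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(
            f"missing or non-finite value in {path} at row {i + 1}, column {j + 1}"
        )
    return arr, cols


def read_character_genotypes(path) -> CodedGenotypes:
    """Read an n x m A/H/B character table and code it.

    A first line containing any token outside {A, H, B} is taken as a header
    row of marker names.
    """
    path = Path(path)
    with _open_text(path) as fh:
        first = fh.readline().split()
    header = any(tok not in GENOTYPE_CODES for tok in first)
    df = pd.read_csv(path, sep=r"\s+", header=0 if header else None, dtype=str)
    marker_ids = [str(c) for c in df.columns] if header else None
    return code_genotypes(df.to_numpy(), marker_ids=marker_ids)


def read_coded_genotypes(z_path, w_path) -> CodedGenotypes:
    """Read user-supplied numeric Z and W tables of identical shape.

    Values are accepted verbatim; the A/H/B pairing constraint is not
    enforced in numeric mode.
    """
    Z, z_cols = _read_numeric_table(z_path)
    W, w_cols = _read_numeric_table(w_path)
    if Z.shape != W.shape:
        raise ValueError(
            f"shape mismatch: {z_path} is {Z.shape}, {w_path} is {W.shape}"
        )
    marker_ids = z_cols or w_cols or []
    return CodedGenotypes(Z, W, marker_ids=list(marker_ids))


def read_phenotype(path, covariates=None, trait_name: str | None = None) -> TraitVector:
    """Read a single-column numeric phenotype file.

    A non-numeric first line is taken as the trait name.  A blank line in the
    interior of the file is a malformed-input error (trailing blank lines are
    tolerated).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise ValueError(f"{path} is empty")
    start = 0
    first = lines[0].strip()
    try:
        float(first.split()[0])
    except (ValueError, IndexError):
        if trait_name is None:
            trait_name = first
        start = 1
    values = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        tok = line.strip()
        if not tok:
            raise ValueError(f"{path}: blank line at line {lineno}")
        try:
            values.append(float(tok.split()[0]))
        except ValueError:
            raise ValueError(
                f"{path}: non-numeric entry {tok!r} at line {lineno}"
            ) from None
    X = covariates if covariates is not None else None
    return TraitVector(np.array(values), X=X, trait_name=trait_name or path.stem)


def read_covariates(path) -> np.ndarray:
    """Read an n x p covariate table and prepend an intercept if needed."""
    arr, _ = _read_numeric_table(path)
    has_constant = any(np.ptp(arr[:, j]) == 0 and arr[0, j] != 0 for j in range(arr.shape[1]))
    if has_constant:
        return arr
    return np.column_stack([np.ones(arr.shape[0]), arr])


# ---------------------------------------------------------------------------
# result writers / readers


def write_kinships(kin, out_dir) -> list[Path]:
    """Write the six kinship matrices as gzip text, one file per component."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for comp in kin.COMPONENTS:
        p = out_dir / KINSHIP_FILE_NAMES[comp]
        K = kin.matrix(comp)
        # fixed mtime and no embedded name keep the bytes deterministic
        with open(p, "wb") as raw, gzip.GzipFile(
            filename="", mode="wb", fileobj=raw, mtime=0
        ) as gz, io.TextIOWrapper(gz) as fh:
            fh.write(f"# component {comp}\n")
            fh.write(f"# norm_constant {kin.norm_constants[comp]:.17g}\n")
            fh.write(f"# normalized {int(kin.normalized)}\n")
            np.savetxt(fh, K, fmt=_FMT)
        paths.append(p)
    return paths


def read_kinships(in_dir):
    """Read six kinship gzip files written by :func:`write_kinships`."""
    from .kinship import KinshipSet  # local import to avoid a cycle

    in_dir = Path(in_dir)
    mats = {}
    constants = {}
    normalized = True
    for comp, name in KINSHIP_FILE_NAMES.items():
        p = in_dir / name
        if not p.exists():
            raise FileNotFoundError(f"missing kinship file {p}")
        constants[comp] = 1.0
        with gzip.open(p, "rt") as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                toks = line[1:].split()
                if toks[:1] == ["norm_constant"]:
                    constants[comp] = float(toks[1])
                elif toks[:1] == ["normalized"]:
                    normalized = bool(int(toks[1]))
        mats[comp] = np.loadtxt(p, comments="#")
        if mats[comp].ndim == 0:
            mats[comp] = mats[comp].reshape(1, 1)
    return KinshipSet(
        K_a=mats["a"], K_d=mats["d"], K_aa=mats["aa"], K_ad=mats["ad"],
        K_da=mats["da"], K_dd=mats["dd"],
        norm_constants=constants, normalized=normalized,
    )


def write_variance_components(vc, path, trait_name: str = "trait") -> Path:
    """Write the variance-component table with a reload-exact footer."""
    from .varcomp import COMPONENTS

    path = Path(path)
    with open(path, "wt") as fh:
        fh.write(f"# trait {trait_name}\n")
        fh.write(f"# loglik {vc.loglik:.17g}\n")
        fh.write(f"# sigma2 {vc.sigma2:.17g}\n")
        fh.write(f"# converged {int(vc.converged)}\n")
        fh.write(f"# n_iter {vc.n_iter}\n")
        fh.write("component\tlambda\tvariance\tproportion\n")
        for i, comp in enumerate(COMPONENTS):
            fh.write(
                f"{comp}\t{vc.lam[i]:.17g}\t{vc.component_variances[i]:.17g}"
                f"\t{vc.proportions[i]:.17g}\n"
            )
        fh.write(f"residual\tNA\t{vc.sigma2:.17g}\t{vc.proportions[6]:.17g}\n")
    return path


def read_variance_components(path):
    from .varcomp import VarianceComponents

    path = Path(path)
    meta: dict[str, str] = {}
    lam, variances, props = [], [], []
    res_prop = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                toks = line[1:].split()
                if len(toks) >= 2:
                    meta[toks[0]] = toks[1]
                continue
            toks = line.split("\t")
            if toks[0] == "component":
                continue
            if toks[0] == "residual":
                res_prop = float(toks[3])
                continue
            lam.append(float(toks[1]))
            variances.append(float(toks[2]))
            props.append(float(toks[3]))
    sigma2 = float(meta["sigma2"])
    return VarianceComponents(
        lam=np.array(lam),
        sigma2=sigma2,
        component_variances=np.array(variances),
        proportions=np.array(props + [res_prop]),
        loglik=float(meta["loglik"]),
        converged=bool(int(meta.get("converged", "1"))),
        n_iter=int(meta.get("n_iter", "0")),
    )


def write_scan1d(res, path) -> Path:
    path = Path(path)
    with open(path, "wt") as fh:
        fh.write("marker_id\tchromosome\tLRT\tphi_a\tphi_d\n")
        chroms = res.chromosomes if res.chromosomes is not None else ["NA"] * len(res.marker_ids)
        for mid, chrom, lrt, pa, pd_ in zip(
            res.marker_ids, chroms, res.lrt, res.phi_a, res.phi_d
        ):
            fh.write(f"{mid}\t{chrom}\t{lrt:.10g}\t{pa:.10g}\t{pd_:.10g}\n")
    return path


def write_scan2d(res, path) -> Path:
    """Write the pairwise scan as a lower-triangular pair listing."""
    path = Path(path)
    with open(path, "wt") as fh:
        fh.write("marker_k\tmarker_kp\tLRT\n")
        for (k, kp), lrt in zip(res.pairs, res.lrt):
            fh.write(f"{res.marker_ids[k]}\t{res.marker_ids[kp]}\t{lrt:.10g}\n")
    return path


def write_outputs(results, out_dir) -> dict:
    """Write every completed stage's files; return the manifest.

    A full run yields six gzip kinship files plus three txt files (variance
    components, 1D scan, 2D scan).  Stages that were not run are simply
    absent from the manifest; file names depend only on the stages run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    if getattr(results, "kinships", None) is not None:
        paths = write_kinships(results.kinships, out_dir)
        manifest["km_cal"] = [p.name for p in paths]
    if getattr(results, "varcomp", None) is not None:
        p = write_variance_components(
            results.varcomp, out_dir / VARCOMP_FILE_NAME,
            trait_name=getattr(results, "trait_name", "trait"),
        )
        manifest["pc_anal"] = [p.name]
    if getattr(results, "scan1d", None) is not None:
        p = write_scan1d(results.scan1d, out_dir / SCAN1D_FILE_NAME)
        manifest["gs_main"] = [p.name]
    if getattr(results, "scan2d", None) is not None:
        p = write_scan2d(results.scan2d, out_dir / SCAN2D_FILE_NAME)
        manifest["gs_epis"] = [p.name]
    with open(out_dir / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
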