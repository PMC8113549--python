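"""Synthetic gene-by-cell UMI matrices with known cell programs.

Generates count matrices that emulate the composition of songbird Area X
tissue — an MSN-dominated mixture with programmed dopamine-receptor/FoxP2
co-occurrence, mitochondrial fractions and high-UMI doublets — so the
snRNA-seq classification chain can be exercised end to end with ground
truth and without any download.

Counts are negative-binomial (gamma-Poisson) per gene with per-program
dispersion; each cell's expected profile is its program's relative means
scaled to a drawn library size.  Receptor/FoxP2 status is sampled *first*
per cell from the program's class probabilities, and the receptor genes'
means are gated on that status (status-positive cells always emit at least
one transcript), so the programmed co-occurrence is recovered exactly by a
value>0 expression rule rather than only in expectation.  Doublets are sums
of two independently drawn cells; with singlet libraries kept under the
10,000-UMI QC threshold, doublet totals exceed it by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from ..snrna import RECEPTOR_CLASSES, flag_mito

__all__ = [
    "CellProgram",
    "SimulationSpec",
    "simulate_counts",
    "area_x_preset",
    "write_10x",
]

MITO_GENES = tuple(f"MT-G{j}" for j in range(1, 11))
RECEPTOR_MEANS = {"Drd1": 3.0, "Drd5": 2.0, "Drd2": 3.0, "FoxP2": 4.0}


@dataclass(frozen=True)
class CellProgram:
    """One cell type's generative program.

    ``markers`` maps gene -> mean UMI per cell (at the reference library
    size); unlisted genes fall back to a low background mean drawn per
    program.  ``receptor_probs`` gives the probabilities of the four
    exclusive dopamine-receptor classes (D1/5-only, D2-only, both, none)
    and ``foxp2_given_class`` the FoxP2+ probability within each class.
    """

    label: str
    proportion: float
    markers: Mapping[str, float] = field(default_factory=dict)
    receptor_probs: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 1.0)
    foxp2_given_class: Mapping[str, float] = field(default_factory=dict)
    lib_mean: float = 6000.0
    lib_sd: float = 600.0
    mito_mean: float = 0.02
    mito_sd: float = 0.008

    def __post_init__(self) -> None:
        if not 0 <= self.proportion <= 1:
            raise ValueError("program proportion out of [0,1]")
        if abs(sum(self.receptor_probs) - 1.0) > 1e-9:
            raise ValueError(f"receptor class probabilities of '{self.label}' must sum to 1")
        if any(p < 0 for p in self.receptor_probs):
            raise ValueError("receptor class probabilities must be >= 0")
        for cls, p in self.foxp2_given_class.items():
            if not 0 <= p <= 1:
                raise ValueError(f"FoxP2 probability for class '{cls}' out of [0,1]")
        if any(m < 0 for m in self.markers.values()):
            raise ValueError("marker means must be >= 0")


@dataclass(frozen=True)
class SimulationSpec:
    """Full specification of a synthetic count matrix."""

    programs: tuple[CellProgram, ...]
    n_cells: int = 10_000
    n_genes: int = 1_000
    doublet_rate: float = 0.03
    dispersion: float = 0.3
    damaged_rate: float = 0.02  # cells with high mito fraction (QC targets)

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be >= 1")
        if not 0 <= self.doublet_rate < 1:
            raise ValueError("doublet_rate out of [0,1)")
        total = sum(p.proportion for p in self.programs)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"program proportions sum to {total}, not 1")


def _gene_universe(spec: SimulationSpec) -> list[str]:
    named: list[str] = []
    seen = set()
    for gene in (*RECEPTOR_MEANS, *MITO_GENES):
        if gene not in seen:
            named.append(gene)
            seen.add(gene)
    for prog in spec.programs:
        for gene in prog.markers:
            if gene not in seen:
                named.append(gene)
                seen.add(gene)
    if len(named) > spec.n_genes:
        raise ValueError(
            f"n_genes={spec.n_genes} too small for {len(named)} named genes"
        )
    background = [f"BG{j:04d}" for j in range(spec.n_genes - len(named))]
    return named + background


def _program_profiles(
    spec: SimulationSpec, genes: list[str], rng: np.random.Generator
) -> np.ndarray:
    """Relative mean matrix (programs x genes), receptor/mito genes zeroed.

    Receptor/FoxP2 and mito contributions are layered per cell afterwards.
    """
    idx = {g: j for j, g in enumerate(genes)}
    gated = set(RECEPTOR_MEANS) | set(MITO_GENES)
    named = {g for prog in spec.programs for g in prog.markers} - gated
    profiles = np.zeros((len(spec.programs), len(genes)))
    for i, prog in enumerate(spec.programs):
        # lognormal background: most genes weak, a long tail of moderate ones
        base = rng.lognormal(mean=np.log(1.0), sigma=1.0, size=len(genes))
        base = np.clip(base, 0.0, 30.0)
        profiles[i] = base
        # marker genes are specific: low uniform background off-program
        for gene in named:
            profiles[i, idx[gene]] = 0.1
        for gene, mean in prog.markers.items():
            profiles[i, idx[gene]] = mean
        for gene in gated:
            profiles[i, idx[gene]] = 0.0
    return profiles


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson sample with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.maximum(mean, 1e-12) / shape)
    return rng.poisson(lam)


def simulate_counts(
    spec: SimulationSpec, seed: int = 0
) -> tuple[AnnData, pd.DataFrame]:
    """Draw a UMI count matrix and its ground-truth cell table.

    Returns an AnnData (cells x genes, raw integer counts, mito genes
    flagged) and a truth DataFrame with the program label, receptor class,
    FoxP2 status, doublet flag and drawn mito fraction per barcode.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_universe(spec)
    idx = {g: j for j, g in enumerate(genes)}
    profiles = _program_profiles(spec, genes, rng)
    props = np.array([p.proportion for p in spec.programs])

    n = spec.n_cells
    n_doublets = int(round(spec.doublet_rate * n))
    n_draws = n + n_doublets  # doublet partners are extra singlet draws

    prog_idx = rng.choice(len(spec.programs), size=n_draws, p=props)
    mito_idx = np.array([idx[g] for g in MITO_GENES])
    receptor_idx = {g: idx[g] for g in RECEPTOR_MEANS}

    counts = np.zeros((n_draws, len(genes)), dtype=np.int64)
    cls_labels = np.empty(n_draws, dtype=object)
    foxp2_flags = np.zeros(n_draws, dtype=bool)
    mito_fracs = np.zeros(n_draws)
    libs = np.zeros(n_draws)

    damaged = rng.random(n_draws) < spec.damaged_rate

    for i, prog in enumerate(spec.programs):
        cells = np.flatnonzero(prog_idx == i)
        if len(cells) == 0:
            continue
        m = len(cells)
        lib = np.clip(rng.normal(prog.lib_mean, prog.lib_sd, size=m), 1500, 9500)
        mito = np.clip(rng.normal(prog.mito_mean, prog.mito_sd, size=m), 0.0, 0.3)
        mito[damaged[cells]] = rng.uniform(0.06, 0.20, size=int(damaged[cells].sum()))
        cls = rng.choice(len(RECEPTOR_CLASSES), size=m, p=np.array(prog.receptor_probs))
        fox_p = np.array(
            [prog.foxp2_given_class.get(RECEPTOR_CLASSES[c], 0.0) for c in cls]
        )
        fox = rng.random(m) < fox_p

        # receptor gene means gated on the sampled status
        gated = np.zeros((m, len(genes)))
        is_d15 = np.isin(cls, [0, 2])  # D1/5-only or both
        is_d2 = np.isin(cls, [1, 2])  # D2-only or both
        d1_on = is_d15 & (rng.random(m) < 0.8)
        d5_on = is_d15 & ~d1_on | (is_d15 & (rng.random(m) < 0.35))
        gated[d1_on, receptor_idx["Drd1"]] = RECEPTOR_MEANS["Drd1"]
        gated[d5_on, receptor_idx["Drd5"]] = RECEPTOR_MEANS["Drd5"]
        gated[is_d2, receptor_idx["Drd2"]] = RECEPTOR_MEANS["Drd2"]
        gated[fox, receptor_idx["FoxP2"]] = RECEPTOR_MEANS["FoxP2"]

        base = np.tile(profiles[i], (m, 1)) + gated
        base_sum = base.sum(axis=1, keepdims=True)
        expected = base / base_sum * (lib * (1.0 - mito))[:, None]
        expected[:, mito_idx] = (lib * mito)[:, None] / len(MITO_GENES)
        c = _nb_counts(expected, spec.dispersion, rng)

        # guarantee >=1 UMI where a status gene is on, 0 where off
        for gene, on in (
            ("Drd1", d1_on),
            ("Drd5", d5_on),
            ("Drd2", is_d2),
            ("FoxP2", fox),
        ):
            j = receptor_idx[gene]
            c[on, j] = np.maximum(c[on, j], 1)
            c[~on, j] = 0

        counts[cells] = c
        cls_labels[cells] = np.array(RECEPTOR_CLASSES, dtype=object)[cls]
        foxp2_flags[cells] = fox
        mito_fracs[cells] = mito
        libs[cells] = lib

    # doublets: overwrite the first n_doublets barcodes with summed pairs
    doublet_flag = np.zeros(n, dtype=bool)
    truth_prog = np.array([spec.programs[i].label for i in prog_idx], dtype=object)
    if n_doublets:
        partners = np.arange(n, n_draws)
        targets = rng.choice(n, size=n_doublets, replace=False)
        counts[targets] += counts[partners]
        doublet_flag[targets] = True
        truth_prog[targets] = np.char.add(
            truth_prog[targets].astype(str), "+doublet"
        )

    counts = counts[:n]
    barcodes = [f"CELL{j:05d}" for j in range(n)]
    adata = AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    flag_mito(adata, mito_genes=list(MITO_GENES))
    truth = pd.DataFrame(
        {
            "program": truth_prog[:n],
            "receptor_class": cls_labels[:n],
            "foxp2_positive": foxp2_flags[:n],
            "doublet": doublet_flag,
            "mito_fraction": mito_fracs[:n],
            "library_size": libs[:n],
            "damaged": damaged[:n],
        },
        index=adata.obs_names,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# Area X preset
# ---------------------------------------------------------------------------

# Receptor-class mix chosen so the MSN-wide aggregate is 36% D1/5-only,
# 13% D2-only, 18% both, 33% none, with Drd2+ cells confined to the
# indirect-like clusters (2, 3, 4).
_DIRECT_CLASSES = (0.55, 0.0, 0.05, 0.40)
_INDIRECT_CLASSES = (0.210714, 0.232143, 0.282143, 0.275)
_FOXP2_BY_CLASS = {"D1/5-only": 0.61, "D2-only": 0.21, "both": 0.40, "none": 0.30}

_MSN_CORE = {"Gad2": 30.0, "Ppp1r1b": 40.0, "FoxP1": 40.0, "Tac1": 20.0, "Meis2": 15.0}


def _signature(name: str, n: int = 15, mean: float = 25.0) -> dict[str, float]:
    return {f"{name}SIG{j:02d}": mean for j in range(1, n + 1)}


def area_x_preset(
    n_cells: int = 10_000,
    n_genes: int = 1_000,
    doublet_rate: float = 0.03,
    drd1_scale: float = 1.0,
) -> SimulationSpec:
    """Packaged Area X composition for recovery testing.

    Programs mirror the tissue's printed composition: five MSN clusters
    totalling 68% of cells (direct-like MSN-1/MSN-5, indirect-like
    MSN-2/3/4), pallidal-like (PN) cells at 2.4%, plus interneuron, glial
    and vascular programs.  The MSN-wide receptor-class split is programmed
    at 36/13/18/33 (D1/5-only / D2-only / both / none) with FoxP2
    co-expression of 61% among D1/5-only and 21% among D2-only cells.

    ``drd1_scale`` < 1 emulates a FoxP2-knockdown-like reduction of Drd1/5
    transcript abundance without changing the class structure.
    """
    del drd1_scale  # applied downstream via scale_receptor_expression
    msn_shares = {"MSN-1": 0.32, "MSN-2": 0.22, "MSN-3": 0.18, "MSN-4": 0.16, "MSN-5": 0.12}
    programs = []
    for name, share in msn_shares.items():
        direct = name in ("MSN-1", "MSN-5")
        programs.append(
            CellProgram(
                label=name,
                proportion=0.68 * share,
                markers={**_MSN_CORE, **_signature(name.replace("-", ""))},
                receptor_probs=_DIRECT_CLASSES if direct else _INDIRECT_CLASSES,
                foxp2_given_class=_FOXP2_BY_CLASS,
            )
        )
    others = [
        CellProgram(
            "PN", 0.024,
            markers={"Penk": 45.0, "Tshz1": 25.0, "Gad2": 15.0, **_signature("PN")},
            foxp2_given_class={"none": 0.05},
        ),
        CellProgram(
            "Int-Pvalb", 0.03,
            markers={"Gad2": 30.0, "Pvalb": 45.0, "Lhx6": 20.0, **_signature("IPV")},
        ),
        CellProgram(
            "Int-Sst", 0.03,
            markers={"Gad2": 30.0, "Sst": 45.0, "Npy": 25.0, "Nos1": 15.0, **_signature("ISST")},
        ),
        CellProgram(
            "Int-Chat", 0.02,
            markers={"Chat": 45.0, "Gad2": 12.0, **_signature("ICH")},
        ),
        CellProgram("Glut", 0.04, markers={"Slc17a6": 45.0, **_signature("GLU")}),
        CellProgram("Astrocyte", 0.066, markers={"Lrig1": 45.0, **_signature("AST")}),
        CellProgram("Oligodendrocyte", 0.06, markers={"Mbp": 55.0, **_signature("OLI")}),
        CellProgram("OPC", 0.02, markers={"Pdgfra": 45.0, **_signature("OPC")}),
        CellProgram("Microglia", 0.02, markers={"Csf1r": 45.0, **_signature("MIC")}),
        CellProgram("Endothelial", 0.01, markers={"Flt1": 45.0, **_signature("END")}),
    ]
    programs.extend(others)
    return SimulationSpec(
        programs=tuple(programs),
        n_cells=n_cells,
        n_genes=n_genes,
        doublet_rate=doublet_rate,
    )


def scale_receptor_expression(
    adata: AnnData, factor: float, genes: Sequence[str] = ("Drd1", "Drd5"), seed: int = 0
) -> AnnData:
    """Binomially thin receptor counts to emulate reduced expression.

    Each UMI of the given genes survives with probability ``factor``
    (status-positive cells keep at least one UMI so classes are stable).
    """
    if not 0 < factor <= 1:
        raise ValueError("factor must be in (0, 1]")
    rng = np.random.default_rng(seed)
    out = adata.copy()
    sparse = sp.issparse(out.X)
    X = out.X.tolil() if sparse else out.X.copy()
    for gene in genes:
        j = out.var_names.get_loc(gene)
        col = np.asarray(
            adata.X[:, [j]].todense() if sparse else adata.X[:, j]
        ).ravel().astype(np.int64)
        thinned = rng.binomial(col, factor)
        thinned[col > 0] = np.maximum(thinned[col > 0], 1)
        if sparse:
            X[:, j] = thinned[:, None]
        else:
            X[:, j] = thinned
    out.X = X.tocsr() if sparse else X
    mito = (
        list(adata.var_names[adata.var["mt"].to_numpy()])
        if "mt" in adata.var
        else None
    )
    return flag_mito(out, mito_genes=mito or None)


def write_10x(adata: AnnData, outdir, truth: pd.DataFrame | None = None) -> None:
    """Write Matrix Market triplets (matrix.mtx, features.tsv, barcodes.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from scipy.io import mmwrite

    # 10x convention stores genes as rows
    mmwrite(str(outdir / "matrix.mtx"), sp.csr_matrix(adata.X).T.astype(int))
    pd.DataFrame(
        {"id": adata.var_names, "name": adata.var_names, "type": "Gene Expression"}
    ).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if truth is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t")
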