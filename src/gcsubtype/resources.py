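"""Packaged reference fixtures and their loaders.

The package ships four small plain-text resources so that no download is
ever required:

* ``reference_signatures_synthetic.tsv`` — a synthetic emulation of four
  reference mutational signatures, named "Signature 1/6/17/29" and shaped
  like their well-known originals (clock-like C>T at NpCpG; mismatch-repair
  C>T; T>G at NpTpT; C>A transversions).  These are NOT the curated COSMIC
  probability tables — they are separable stand-ins for simulation and
  testing.  ``read_reference_signatures`` accepts a real COSMIC v2 file
  whenever one is available.
* ``gene_model_synthetic.tsv`` — ~200 genes with approximate genomic
  coordinates and coding lengths, covering the recurrently altered gastric
  cancer genes plus anonymous filler genes; synthetic, for simulation.
* ``cgc_genes_synthetic.tsv`` — a curated subset of cancer-gene-census-style
  symbols used by the essential-alteration selection rules.
* ``pathway_genes_synthetic.tsv`` — gene -> pathway map for the four key
  pathways (RTK/RAS/PI3K, p53/cell cycle, cell adhesion, chromatin
  remodeling).

Each builder below regenerates its fixture deterministically; running this
module as a script rewrites the packaged files.
"""

from __future__ import annotations

from importlib import resources as _ilr
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import BASES, CHANNEL_ORDER
from .types import ReferenceSignatureSet

_DATA = _ilr.files("gcsubtype") / "data"


# ---------------------------------------------------------------------------
# reference signatures


def _signature_profile(sub_weights: dict[str, float], flank_bias: dict[str, dict[str, float]],
                       background: float) -> np.ndarray:
    """Assemble one 96-channel probability vector.

    ``sub_weights`` distributes mass over the six substitution types;
    ``flank_bias`` optionally reweights 5'/3' flanking bases per type.
    A flat ``background`` fraction keeps every channel strictly positive.
    """
    profile = np.zeros(96)
    for i, channel in enumerate(CHANNEL_ORDER):
        sub = channel[2:5]
        if sub not in sub_weights:
            continue
        five, three = channel[0], channel[6]
        bias = flank_bias.get(sub, {})
        w5 = bias.get("five", {}).get(five, 1.0) if isinstance(bias.get("five"), dict) else 1.0
        w3 = bias.get("three", {}).get(three, 1.0) if isinstance(bias.get("three"), dict) else 1.0
        profile[i] = sub_weights[sub] * w5 * w3
    profile = profile / profile.sum()
    profile = (1 - background) * profile + background / 96
    return profile / profile.sum()


def build_reference_signatures() -> ReferenceSignatureSet:
    """Synthetic four-signature bank (see module docstring)."""
    sig1 = _signature_profile(  # clock-like: C>T at NpCpG
        {"C>T": 1.0},
        {"C>T": {"three": {"G": 20.0, "A": 0.5, "C": 0.5, "T": 0.5}}},
        background=0.03,
    )
    sig6 = _signature_profile(  # mismatch-repair-like: C>T at G-5' contexts, some C>A
        {"C>T": 0.8, "C>A": 0.2},
        {"C>T": {"five": {"G": 10.0, "A": 1.0, "C": 2.0, "T": 0.5},
                 "three": {"G": 0.2, "A": 1.5, "C": 1.5, "T": 1.0}}},
        background=0.05,
    )
    sig17 = _signature_profile(  # T>G at NpTpT with minor T>C
        {"T>G": 0.85, "T>C": 0.15},
        {"T>G": {"five": {"C": 8.0, "A": 1.0, "G": 0.5, "T": 2.0},
                 "three": {"T": 15.0, "A": 0.3, "C": 0.3, "G": 0.3}}},
        background=0.03,
    )
    sig29 = _signature_profile(  # tobacco-like C>A transversions
        {"C>A": 0.9, "C>G": 0.1},
        {"C>A": {"five": {"C": 3.0, "T": 2.0, "A": 1.0, "G": 1.0},
                 "three": {"A": 2.5, "C": 1.5, "G": 0.5, "T": 1.0}}},
        background=0.05,
    )
    matrix = np.column_stack([sig1, sig6, sig17, sig29])
    names = ["Signature 1", "Signature 6", "Signature 17", "Signature 29"]
    return ReferenceSignatureSet(names=names, matrix=matrix)


def load_reference_signatures() -> ReferenceSignatureSet:
    from .io import read_reference_signatures

    with _ilr.as_file(_DATA / "reference_signatures_synthetic.tsv") as path:
        return read_reference_signatures(path)


# ---------------------------------------------------------------------------
# gene model

_CURATED_GENES = [
    # gene, chrom, start, end, coding_length  (approximate hg19 locations)
    ("ARID1A", "1", 27022522, 27108601, 6858),
    ("SPTA1", "1", 158580496, 158656505, 7260),
    ("LRP1B", "2", 140988996, 142889270, 13800),
    ("TTN", "2", 179390716, 179695529, 100000),
    ("FSIP2", "2", 186602934, 186680898, 20000),
    ("ITGAV", "2", 187454792, 187545420, 3144),
    ("MLH1", "3", 37034841, 37107338, 2271),
    ("CTNNB1", "3", 41236328, 41301587, 2346),
    ("RHOA", "3", 49396578, 49412998, 582),
    ("PIK3CA", "3", 178866311, 178957881, 3207),
    ("MUC4", "3", 195473637, 195538844, 16000),
    ("FAT4", "4", 126237554, 126414087, 14946),
    ("APC", "5", 112043195, 112181936, 8532),
    ("CCND3", "6", 41902671, 42018922, 879),
    ("VEGFA", "6", 43737946, 43754224, 1239),
    ("HSP90AB1", "6", 44214824, 44221613, 2175),
    ("SYNE1", "6", 152442819, 152958936, 26000),
    ("EGFR", "7", 55086725, 55324313, 3633),
    ("KMT2C", "7", 151832010, 152133090, 14736),
    ("PREX2", "8", 68864353, 69149263, 4824),
    ("CSMD3", "8", 113235157, 114449328, 11000),
    ("MYC", "8", 128748315, 128753680, 1320),
    ("CDKN2A", "9", 21967751, 21995300, 471),
    ("NOTCH1", "9", 139388896, 139440314, 7668),
    ("PTEN", "10", 89623195, 89728532, 1212),
    ("CCND1", "11", 69455873, 69469242, 888),
    ("FAT3", "11", 92085262, 92629618, 13700),
    ("KRAS", "12", 25358180, 25403870, 570),
    ("KMT2D", "12", 49412758, 49453557, 16614),
    ("CDK4", "12", 58141510, 58149796, 912),
    ("MDM2", "12", 69201956, 69239214, 1494),
    ("TRHDE", "12", 72666074, 73059422, 3060),
    ("CDH1", "16", 68771195, 68869444, 2649),
    ("PIEZO1", "16", 88776541, 88851260, 7566),
    ("TP53", "17", 7571720, 7590868, 1182),
    ("ERBB2", "17", 37844393, 37884915, 3768),
    ("BRCA1", "17", 41196312, 41277500, 5592),
    ("SMAD4", "18", 48556583, 48611411, 1659),
    ("SMARCA4", "19", 11071598, 11176958, 4944),
    ("CCNE1", "19", 30302805, 30315215, 1233),
]

N_FILLER_GENES = 160


def build_gene_model() -> pd.DataFrame:
    """~200-gene synthetic gene model, curated genes plus anonymous filler."""
    rng = np.random.default_rng(20210606)
    rows = list(_CURATED_GENES)
    chroms = [str(c) for c in range(1, 23)]
    for i in range(N_FILLER_GENES):
        chrom = chroms[i % len(chroms)]
        start = int(rng.integers(1_000_000, 200_000_000))
        length = int(rng.integers(20_000, 300_000))
        coding = int(np.clip(rng.lognormal(np.log(1500), 0.6), 300, 30000))
        rows.append((f"GENE{i + 1:03d}", chrom, start, start + length, coding))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "coding_length"])
    chrom_key = df["chrom"].map(lambda c: int(c))
    df = df.loc[np.lexsort((df["start"], chrom_key))].reset_index(drop=True)
    return df


def load_gene_model() -> pd.DataFrame:
    with _ilr.as_file(_DATA / "gene_model_synthetic.tsv") as path:
        return pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")


# ---------------------------------------------------------------------------
# cancer gene census subset / pathway genes

_CGC_GENES = [
    "TP53", "ARID1A", "PIK3CA", "CDH1", "RHOA", "SMAD4", "ERBB2", "CCNE1",
    "CCND1", "CCND3", "CDK4", "KMT2C", "KMT2D", "SMARCA4", "FAT4", "FAT3",
    "LRP1B", "MLH1", "CDKN2A", "BRCA1", "MYC", "NOTCH1", "PTEN", "KRAS",
    "APC", "CTNNB1", "EGFR", "PREX2", "SPTA1", "SYNE1", "MDM2", "VEGFA",
    "HSP90AB1", "ITGAV",
]

_PATHWAYS = {
    "RTK_RAS_PI3K": ["ERBB2", "HSP90AB1", "MYC", "PIK3CA", "KRAS", "EGFR",
                     "VEGFA", "PTEN", "PREX2"],
    "p53_cell_cycle": ["TP53", "CCNE1", "CCND1", "CCND3", "CDK4", "CDKN2A",
                       "MDM2"],
    "cell_adhesion": ["CDH1", "RHOA", "ITGAV", "CTNNB1", "FAT4", "APC"],
    "chromatin_remodeling": ["ARID1A", "SMARCA4", "KMT2C", "KMT2D"],
}


def build_cgc_genes() -> pd.DataFrame:
    return pd.DataFrame({"gene": sorted(_CGC_GENES)})


def load_cgc_genes() -> set[str]:
    with _ilr.as_file(_DATA / "cgc_genes_synthetic.tsv") as path:
        return set(pd.read_csv(path, sep="\t", comment="#")["gene"])


def build_pathway_genes() -> pd.DataFrame:
    rows = [(g, p) for p, genes in _PATHWAYS.items() for g in genes]
    return pd.DataFrame(rows, columns=["gene", "pathway"])


def load_pathway_genes() -> set[str]:
    with _ilr.as_file(_DATA / "pathway_genes_synthetic.tsv") as path:
        return set(pd.read_csv(path, sep="\t", comment="#")["gene"])


_HEADERS = {
    "reference_signatures_synthetic.tsv":
        "# Synthetic emulation of four reference mutational signatures "
        "(NOT the curated COSMIC tables); regenerate with "
        "`python -m gcsubtype.resources`.",
    "gene_model_synthetic.tsv":
        "# Synthetic ~200-gene model (approximate coordinates, for simulation); "
        "regenerate with `python -m gcsubtype.resources`.",
    "cgc_genes_synthetic.tsv":
        "# Curated cancer-gene-census-style subset (synthetic fixture, frozen "
        "so results do not drift with database versions).",
    "pathway_genes_synthetic.tsv":
        "# Key-pathway gene map (RTK/RAS/PI3K, p53/cell cycle, cell adhesion, "
        "chromatin remodeling); synthetic fixture.",
}


def regenerate(data_dir: Path | None = None) -> None:
    from .io import write_reference_signatures

    data_dir = Path(data_dir) if data_dir else Path(str(_DATA))
    data_dir.mkdir(parents=True, exist_ok=True)

    def _write(name: str, writer) -> None:
        path = data_dir / name
        tmp = path.with_suffix(".tmp")
        writer(tmp)
        path.write_text(_HEADERS[name] + "\n" + tmp.read_text())
        tmp.unlink()

    _write("reference_signatures_synthetic.tsv",
           lambda p: write_reference_signatures(build_reference_signatures(), p))
    _write("gene_model_synthetic.tsv",
           lambda p: build_gene_model().to_csv(p, sep="\t", index=False))
    _write("cgc_genes_synthetic.tsv",
           lambda p: build_cgc_genes().to_csv(p, sep="\t", index=False))
    _write("pathway_genes_synthetic.tsv",
           lambda p: build_pathway_genes().to_csv(p, sep="\t", index=False))


if __name__ == "__main__":
    regenerate()
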