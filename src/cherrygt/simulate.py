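"""Synthetic-data generation for every stage of the pipeline.

Emulates the two-round PCR amplicon construct end to end: read 1 carries
the 6-bp i5 barcode, the OH1 adapter, the locus forward primer, and the
SNP-bearing insert; read 2 mirrors this with i7/OH2/reverse primer on the
reverse-complement strand.  Heterozygotes emit either allele per read
with probability 1/2 (per-read Bernoulli, the simplest model consistent
with amplicon PCR); sequencing noise is uniform substitution at a fixed
per-base rate, no indels.  Also generates chromatophore-cluster images
and qPCR Ct tables for the phenotype and expression endpoints.
"""

from __future__ import annotations

import gzip as gzip_mod
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ._seq import decode_rows, deterministic_sequence, encode, revcomp
from .panel import BarcodePanel, SampleSheet, SnpLocus

GENOTYPES = ("hom_ref", "het", "hom_alt")
READ_LENGTH = 150
QUALITY_CHAR = "?"  # constant Phred 30; the pipeline never consumes qualities

# Default study conditions: four colour strains of 192 individuals in two
# pools; only the yellow strain segregates at the two coding SNPs.
DEFAULT_N_PER_STRAIN = 192
DEFAULT_P_HET_YELLOW = 0.3
DEFAULT_DEPTH = 200
DEFAULT_ERROR_RATE = 0.005


@dataclass(frozen=True)
class StrainGenotypeSpec:
    """Per-locus genotype probabilities for one strain."""

    strain: str
    locus_probs: dict[str, tuple[float, float, float]]  # (hom_ref, het, hom_alt)

    def validate(self) -> None:
        for locus_id, probs in self.locus_probs.items():
            if len(probs) != 3 or any(p < 0 or p > 1 for p in probs):
                raise ValueError(
                    f"{self.strain}/{locus_id}: probabilities must be three values in [0,1]")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.strain}/{locus_id}: probabilities sum to {sum(probs)}, not 1")


def default_strain_specs(loci: list[SnpLocus],
                         p_het_yellow: float = DEFAULT_P_HET_YELLOW) -> list[StrainGenotypeSpec]:
    """Default scenario: yellow segregates, the other strains are fixed hom-ref."""
    specs = []
    for strain in ("red", "yellow", "blue", "wild"):
        if strain == "yellow":
            probs = (1.0 - p_het_yellow, p_het_yellow, 0.0)
        else:
            probs = (1.0, 0.0, 0.0)
        specs.append(StrainGenotypeSpec(
            strain=strain, locus_probs={loc.locus_id: probs for loc in loci}))
    return specs


def draw_truth_genotypes(specs: list[StrainGenotypeSpec], n_per_strain: int,
                         seed: int) -> pd.DataFrame:
    """Draw ground-truth genotypes, one row per individual x locus.

    Individuals are named ``<strain>_<k>`` to match the default sample
    sheet; genotypes are drawn independently per locus.
    """
    if n_per_strain < 1:
        raise ValueError("n_per_strain must be >= 1")
    for spec in specs:
        spec.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        for locus_id, probs in spec.locus_probs.items():
            draws = rng.choice(3, size=n_per_strain, p=probs)
            for k, g in enumerate(draws):
                rows.append((f"{spec.strain}_{k + 1:03d}", spec.strain,
                             locus_id, GENOTYPES[g]))
    return pd.DataFrame(rows, columns=["individual_id", "strain", "locus_id", "genotype"])


def write_truth_csv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def read_truth_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# amplicon construction

def build_amplicon(locus: SnpLocus, allele: str) -> str:
    """Reference-strand amplicon carrying ``allele`` at the SNP position.

    Layout: forward primer + filler + revcomp(reverse primer), total
    ``amplicon_length`` bases.  Filler is keyed on the locus id alone so
    the synthetic reference is stable across runs and seeds.
    """
    fp, rp = locus.forward_primer, locus.reverse_primer
    insert_len = locus.amplicon_length - len(fp) - len(rp)
    if insert_len < locus.snp_offset:
        raise ValueError(
            f"{locus.locus_id}: SNP offset {locus.snp_offset} does not fit in the "
            f"{insert_len}-bp insert between the primers")
    filler = deterministic_sequence(f"amplicon:{locus.locus_id}", insert_len)
    snp_i = locus.snp_offset - 1  # within the filler
    seq = fp + filler[:snp_i] + allele + filler[snp_i + 1:] + revcomp(rp)
    assert len(seq) == locus.amplicon_length
    return seq


def _read_templates(locus: SnpLocus, barcodes: BarcodePanel, i5: str, i7: str,
                    read_length: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Encoded (r1_ref, r1_alt, r2_ref, r2_alt) templates for one sample x locus."""
    out = []
    for allele in (locus.ref_allele, locus.alt_allele):
        amp = build_amplicon(locus, allele)
        r1 = (i5 + barcodes.oh1 + amp)[:read_length]
        r2 = (i7 + barcodes.oh2 + revcomp(amp))[:read_length]
        out.append((encode(r1), encode(r2)))
    (r1_ref, r2_ref), (r1_alt, r2_alt) = out
    return r1_ref, r1_alt, r2_ref, r2_alt


def _inject_errors(codes: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    if error_rate <= 0:
        return codes
    mask = rng.random(codes.shape) < error_rate
    n = int(mask.sum())
    if n:
        codes = codes.copy()
        # shift by 1..3 mod 4 => always a different base, uniform over the other three
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return codes


def simulate_library(loci: list[SnpLocus], barcodes: BarcodePanel, sheet: SampleSheet,
                     truth: pd.DataFrame, depth_per_locus: int, error_rate: float,
                     seed: int, out_dir: str | Path, read_length: int = READ_LENGTH,
                     gzip: bool = False) -> dict[str, tuple[Path, Path]]:
    """Write one paired-FASTQ library per pool plus a truth manifest.

    Every individual x locus contributes exactly ``depth_per_locus``
    read pairs.  Read names encode pool, individual, locus, and serial
    number so round-trip tests can compare demultiplexing against truth
    without side tables.  Returns ``{pool_id: (r1_path, r2_path)}``.
    """
    if depth_per_locus <= 0:
        raise ValueError("depth_per_locus must be positive")
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    truth_map = {(r.individual_id, r.locus_id): r.genotype
                 for r in truth.itertuples(index=False)}
    missing = [r.individual_id for r in sheet.records
               if any((r.individual_id, loc.locus_id) not in truth_map for loc in loci)]
    if missing:
        raise ValueError(f"truth genotypes missing for individuals: {sorted(set(missing))[:5]} ...")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    qline = QUALITY_CHAR * read_length
    paths: dict[str, tuple[Path, Path]] = {}

    for pool_id, records in sheet.by_pool().items():
        suffix = ".fastq.gz" if gzip else ".fastq"
        p1 = out_dir / f"pool_{pool_id}_R1{suffix}"
        p2 = out_dir / f"pool_{pool_id}_R2{suffix}"
        opener = gzip_mod.open if gzip else open
        with opener(p1, "wt") as f1, opener(p2, "wt") as f2:
            for rec in records:
                for locus in loci:
                    geno = truth_map[(rec.individual_id, locus.locus_id)]
                    r1_ref, r1_alt, r2_ref, r2_alt = _read_templates(
                        locus, barcodes, rec.i5_tag, rec.i7_tag, read_length)
                    if geno == "hom_ref":
                        alt_flag = np.zeros(depth_per_locus, dtype=bool)
                    elif geno == "hom_alt":
                        alt_flag = np.ones(depth_per_locus, dtype=bool)
                    else:
                        alt_flag = rng.random(depth_per_locus) < 0.5
                    m1 = np.where(alt_flag[:, None], r1_alt[None, :], r1_ref[None, :])
                    m2 = np.where(alt_flag[:, None], r2_alt[None, :], r2_ref[None, :])
                    m1 = _inject_errors(m1, error_rate, rng)
                    m2 = _inject_errors(m2, error_rate, rng)
                    q1 = qline[:m1.shape[1]]
                    q2 = qline[:m2.shape[1]]
                    seqs1 = decode_rows(m1)
                    seqs2 = decode_rows(m2)
                    chunk1, chunk2 = [], []
                    for i, (s1, s2) in enumerate(zip(seqs1, seqs2)):
                        name = f"{pool_id}|{rec.individual_id}|{locus.locus_id}|{i}"
                        chunk1.append(f"@{name}\n{s1}\n+\n{q1}")
                        chunk2.append(f"@{name}\n{s2}\n+\n{q2}")
                    f1.write("\n".join(chunk1) + "\n")
                    f2.write("\n".join(chunk2) + "\n")
        paths[pool_id] = (p1, p2)

    write_truth_csv(truth, out_dir / "truth_genotypes.csv")
    return paths


# ---------------------------------------------------------------------------
# image and Ct-table fixtures

@dataclass(frozen=True)
class ClusterGeometry:
    """Elliptical chromatophore-cluster shape in pixels."""

    semi_major: float
    semi_minor: float
    rotate: bool = True

    def validate(self) -> None:
        if self.semi_major <= 0 or self.semi_minor <= 0:
            raise ValueError("cluster axes must be positive")
        if self.semi_minor > self.semi_major:
            raise ValueError("semi_minor must not exceed semi_major")


def simulate_images(n_clusters: int, cluster_geometry: ClusterGeometry,
                    redness_level: float, background: int, seed: int,
                    image_size: tuple[int, int] = (256, 256)
                    ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render elliptical red-dominant clusters on a neutral grey background.

    ``redness_level`` is the target red-to-total brightness ratio of
    cluster pixels (>= 1/3 for red dominance); the truth table records
    the RPB actually painted after 8-bit quantisation, plus each
    cluster's centre, axes lengths, and orientation.
    """
    from skimage.draw import ellipse

    cluster_geometry.validate()
    h, w = image_size
    if 2 * cluster_geometry.semi_major + 2 > min(h, w):
        raise ValueError("cluster larger than the image allows")
    if not (1 / 3 <= redness_level <= 1):
        raise ValueError("redness_level must be in [1/3, 1] for a red-dominant cluster")

    rng = np.random.default_rng(seed)
    img = np.full((h, w, 3), background, dtype=np.uint8)

    # constant-total colour: R = redness * T, G = B = (T - R) / 2
    total = 240.0
    r_val = int(round(redness_level * total))
    gb_val = int(round((total - r_val) / 2))
    rpb_painted = r_val / (r_val + 2 * gb_val)

    # place clusters on a jittered grid so they never merge
    cell = int(2 * cluster_geometry.semi_major) + 8
    cols = max(1, w // cell)
    rows_ = []
    for k in range(n_clusters):
        gi, gj = divmod(k, cols)
        cy = gi * cell + cell // 2
        cx = gj * cell + cell // 2
        if cy + cell // 2 > h or cx + cell // 2 > w:
            raise ValueError(f"image too small for {n_clusters} non-overlapping clusters")
        angle = float(rng.uniform(0, np.pi)) if cluster_geometry.rotate else 0.0
        rr, cc = ellipse(cy, cx, cluster_geometry.semi_major,
                         cluster_geometry.semi_minor, shape=(h, w), rotation=angle)
        img[rr, cc] = (r_val, gb_val, gb_val)
        rows_.append((k, cy, cx, 2 * cluster_geometry.semi_major,
                      2 * cluster_geometry.semi_minor, np.degrees(angle),
                      rpb_painted, len(rr)))
    truth = pd.DataFrame(rows_, columns=[
        "cluster_id", "center_row", "center_col", "length", "width",
        "angle_deg", "rpb", "n_pixels"])
    return img, truth


def save_png(img: np.ndarray, path: str | Path) -> None:
    Image.fromarray(img).save(path)


def load_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def simulate_ct_table(group_means: dict[str, float], sd: float, n_per_group: int,
                      seed: int, reference_ct: float = 20.0,
                      target_gene: str = "ninab_like",
                      reference_gene: str = "gapdh") -> pd.DataFrame:
    """qPCR Ct records with the stated per-group deltaCt mean and spread.

    The reference-gene Ct is held constant and all variation is placed on
    the target Ct, so each group's deltaCt has exactly the requested mean
    and standard deviation.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for group, mean_dct in group_means.items():
        noise = rng.normal(0.0, sd, size=n_per_group) if sd > 0 else np.zeros(n_per_group)
        for k in range(n_per_group):
            rows.append((f"{group}_{k + 1:02d}", group, target_gene, reference_gene,
                         reference_ct + mean_dct + noise[k], reference_ct))
    return pd.DataFrame(rows, columns=[
        "sample_id", "group", "target_gene", "reference_gene",
        "target_ct", "reference_ct"])
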