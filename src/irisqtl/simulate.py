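"""Synthetic study generator.

Produces every input the pipeline consumes — iris photographs with
masks, pedigrees, Mendelian genotypes, kinship-structured phenotypes,
mixture-distributed phenotype samples, and aligned haplotypes with an
outgroup — together with the ground truth used by recovery tests.

The generators encode the statistical structure the analysis assumes:
iris pixels are a base CIELAB color plus i.i.d. Gaussian sensor noise
with planted achromatic highlights and shadows; phenotypes follow
``y = W alpha + x beta + u + e`` with a pedigree-kinship random effect;
and phenotype distributions are one- or two-component Gaussian
mixtures.  Default group sizes mirror a realistic multi-species study
design (8 lemurs, 33 captive + 19 wild macaques, 119 humans, 6 spider
monkeys).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colorimetry import IrisImage, lab_to_srgb
from .kinship import Pedigree, kinship_from_pedigree, relatedness

__all__ = [
    "ImageConfig",
    "PedigreeConfig",
    "GeneticsConfig",
    "PhenotypeConfig",
    "ClusterConfig",
    "SyntheticConfig",
    "gen_iris_image",
    "gen_pedigree",
    "gen_genotypes",
    "gen_phenotypes",
    "gen_cluster_sample",
    "gen_alignment",
    "DEFAULT_GROUP_SIZES",
]

DEFAULT_GROUP_SIZES = {
    "lemur": 8,
    "macaque_captive": 33,
    "macaque_wild": 19,
    "human": 119,
    "spider_monkey": 6,
}


@dataclass
class ImageConfig:
    size: tuple[int, int] = (64, 64)
    center: tuple[float, float] = (32.0, 32.0)
    radii: tuple[float, float] = (20.0, 14.0)
    base_lab: tuple[float, float, float] = (55.0, -5.0, -20.0)  # a blue iris
    noise_sd: float = 3.0
    n_highlight: int = 40
    n_shadow: int = 25


@dataclass
class PedigreeConfig:
    n_founders: int = 20
    n_generations: int = 3
    mean_offspring: float = 2.0


@dataclass
class GeneticsConfig:
    n_variants: int = 11
    causal_index: int = 5
    founder_freq: float = 0.3
    beta: float = 1.0


@dataclass
class PhenotypeConfig:
    sigma_g2: float = 1.0
    sigma_e2: float = 1.0
    alpha: tuple = (0.0,)  # intercept plus any covariate effects


@dataclass
class ClusterConfig:
    means: tuple[float, float] = (0.0, 4.0)
    sds: tuple[float, float] = (1.0, 1.0)
    weights: tuple[float, float] = (0.5, 0.5)
    n: int = 8


@dataclass
class SyntheticConfig:
    seed: int = 0
    image: ImageConfig = field(default_factory=ImageConfig)
    pedigree: PedigreeConfig = field(default_factory=PedigreeConfig)
    genetics: GeneticsConfig = field(default_factory=GeneticsConfig)
    phenotype: PhenotypeConfig = field(default_factory=PhenotypeConfig)
    clusters: ClusterConfig = field(default_factory=ClusterConfig)


def gen_iris_image(cfg: ImageConfig, rng=None, image_id="sim", encoding_tag="synthetic"):
    """Synthetic iris photograph with mask and known base color.

    The iris ellipse is filled with the sRGB rendering of ``base_lab``
    plus i.i.d. Gaussian channel noise (clipped into the retained range
    [10, 250] so noise cannot masquerade as an artifact), then exactly
    ``n_highlight`` achromatic highlight pixels (all channels > 250)
    and ``n_shadow`` shadow pixels (all channels < 10) are planted
    inside the mask.  Returns ``(IrisImage, base_lab)``.
    """
    from skimage.draw import ellipse

    rng = np.random.default_rng(rng)
    h, w = cfg.size
    base_rgb = lab_to_srgb(np.asarray(cfg.base_lab, dtype=float))  # raises if out of gamut
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = ellipse(cfg.center[0], cfg.center[1], cfg.radii[0], cfg.radii[1], shape=(h, w))
    mask[rr, cc] = True
    n_mask = int(mask.sum())
    if cfg.n_highlight + cfg.n_shadow >= n_mask:
        raise ValueError("planted artifacts would consume the whole iris")

    pixels = np.full((h, w, 3), 200, dtype=np.uint8)  # bland background
    noisy = base_rgb[None, :] + rng.normal(0.0, cfg.noise_sd, size=(n_mask, 3))
    # keep iris pixels inside the retained range so only planted
    # artifacts are filtered downstream
    noisy = np.clip(np.rint(noisy), 10, 250).astype(np.uint8)
    pixels[mask] = noisy

    idx = rng.choice(n_mask, size=cfg.n_highlight + cfg.n_shadow, replace=False)
    ys, xs = np.nonzero(mask)
    hi, sh = idx[: cfg.n_highlight], idx[cfg.n_highlight :]
    pixels[ys[hi], xs[hi]] = rng.integers(251, 256, size=(cfg.n_highlight, 3))
    pixels[ys[sh], xs[sh]] = rng.integers(0, 10, size=(cfg.n_shadow, 3))

    return IrisImage(pixels, mask, image_id=image_id, encoding_tag=encoding_tag), tuple(cfg.base_lab)


def gen_pedigree(cfg: PedigreeConfig, rng=None, prefix="I") -> Pedigree:
    """Random-mating pedigree over discrete generations.

    Founders (generation 0) get alternating sexes; each later
    generation draws a Poisson(mean_offspring) brood per mated pair,
    pairing random males and females from all earlier generations.
    """
    rng = np.random.default_rng(rng)
    if cfg.n_founders < 2:
        raise ValueError("need at least 2 founders")
    rows = []
    males, females = [], []
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:04d}"

    for i in range(cfg.n_founders):
        iid = new_id()
        sex = "M" if i % 2 == 0 else "F"
        (males if sex == "M" else females).append(iid)
        rows.append((iid, "NA", "NA", sex, "founder"))
    for g in range(1, cfg.n_generations + 1):
        n_pairs = max(1, min(len(males), len(females)) // 2)
        sires = rng.choice(males, size=n_pairs, replace=False)
        dams = rng.choice(females, size=n_pairs, replace=False)
        new_m, new_f = [], []
        for s, d in zip(sires, dams):
            for _ in range(rng.poisson(cfg.mean_offspring)):
                iid = new_id()
                sex = "M" if rng.random() < 0.5 else "F"
                (new_m if sex == "M" else new_f).append(iid)
                rows.append((iid, s, d, sex, f"gen{g}"))
        males += new_m
        females += new_f
    return Pedigree(rows)


def gen_genotypes(ped: Pedigree, cfg: GeneticsConfig, rng=None):
    """Mendelian gene dropping of biallelic variants down a pedigree.

    Founder haplotypes carry the derived allele i.i.d. with probability
    ``founder_freq`` per variant; each offspring inherits one uniformly
    chosen haplotype from each parent.  Returns ``(dosages, haplotypes)``:
    a DataFrame of {0,1,2} dosages (individuals x variants) and the
    underlying (n, 2, n_variants) 0/1 haplotype array.
    """
    rng = np.random.default_rng(rng)
    ids = ped.ids
    pos = {v: i for i, v in enumerate(ids)}
    parents = {r.individual_id: (r.sire_id, r.dam_id) for r in ped.records}
    hap = np.zeros((len(ids), 2, cfg.n_variants), dtype=np.int8)
    for ind in ped._topo:
        i = pos[ind]
        f, m = parents[ind]
        for slot, par in enumerate((f, m)):
            if par is None:
                hap[i, slot] = rng.random(cfg.n_variants) < cfg.founder_freq
            else:
                which = rng.integers(0, 2, size=cfg.n_variants)
                hap[i, slot] = hap[pos[par], which, np.arange(cfg.n_variants)]
    dosage = hap.sum(axis=1)
    cols = [f"v{j}" for j in range(cfg.n_variants)]
    return pd.DataFrame(dosage, index=ids, columns=cols), hap


def gen_phenotypes(
    ped: Pedigree,
    genotypes: pd.DataFrame,
    cfg: PhenotypeConfig,
    gcfg: GeneticsConfig,
    rng=None,
    covariates=None,
):
    """Phenotypes from the generative mixed model.

    ``y = W alpha + x_causal beta + u + e`` with
    ``u ~ N(0, sigma_g2 * K)`` (K = 2 phi from the pedigree) and
    ``e ~ N(0, sigma_e2 * I)``.  ``covariates`` is an optional (n, p)
    design whose columns follow the intercept in ``alpha``.

    Returns ``(y, truth)`` where truth records beta, the variance
    components, K, and the causal column name.
    """
    rng = np.random.default_rng(rng)
    ids = ped.ids
    n = len(ids)
    kin = kinship_from_pedigree(ped)
    K = relatedness(kin)

    W = np.ones((n, 1))
    if covariates is not None:
        W = np.column_stack([W, covariates])
    alpha = np.asarray(cfg.alpha, dtype=float)
    if alpha.size != W.shape[1]:
        raise ValueError("alpha length must match intercept + covariates")

    causal = f"v{gcfg.causal_index}"
    x = genotypes.loc[ids, causal].to_numpy(dtype=float)

    # draw u via the eigendecomposition (K is PSD by construction)
    s, U = np.linalg.eigh(K)
    s = np.maximum(s, 0.0)
    u = U @ (np.sqrt(cfg.sigma_g2 * s) * rng.standard_normal(n))
    e = rng.normal(0.0, np.sqrt(cfg.sigma_e2), size=n)
    y = W @ alpha + x * gcfg.beta + u + e
    truth = {
        "beta": gcfg.beta,
        "sigma_g2": cfg.sigma_g2,
        "sigma_e2": cfg.sigma_e2,
        "causal": causal,
        "K": K,
        "kinship": kin,
        "ids": ids,
    }
    return pd.Series(y, index=ids, name="phenotype"), truth


def gen_cluster_sample(cfg: ClusterConfig, rng=None) -> np.ndarray:
    """i.i.d. draws from a two-component normal mixture (or a single
    normal when one weight is 1)."""
    rng = np.random.default_rng(rng)
    w = np.asarray(cfg.weights, dtype=float)
    if w.min() < 0 or abs(w.sum() - 1) > 1e-12:
        raise ValueError("weights must be nonnegative and sum to 1")
    comp = rng.choice(2, size=cfg.n, p=w)
    mus = np.asarray(cfg.means, dtype=float)[comp]
    sds = np.asarray(cfg.sds, dtype=float)[comp]
    return rng.normal(mus, sds)


def gen_alignment(
    n_haplotypes: int = 12,
    length: int = 120,
    anchor_column: int = 60,
    planted_offsets=(-30, -6, 20),
    carrier_fraction: float = 0.4,
    n_ref_gap_columns: int = 0,
    groups=None,
    rng=None,
):
    """Aligned ingroup haplotypes plus outgroup with planted variants.

    A random reference sequence is generated; at each planted offset a
    derived base (a transition of the ancestral base) is assigned to a
    random subset of ingroup haplotypes while the outgroup keeps the
    ancestral state.  ``n_ref_gap_columns`` inserts alignment columns
    in which the outgroup/reference is gapped (so they carry no
    anchored coordinate).  Returns ``(AlignedHaplotypes, truth)`` with
    the planted offsets, polarity, and carrier frequencies.

    Ingroup haplotype ids are ``h00, h01, ...``; ``groups`` optionally
    maps them to group labels (default: single group ``"pop"``, all
    founders).
    """
    from .variants import AlignedHaplotypes

    rng = np.random.default_rng(rng)
    offsets = sorted(set(int(o) for o in planted_offsets))
    if len(offsets) != len(tuple(planted_offsets)):
        raise ValueError("planted offsets collide")
    bases = np.array(list("ACGT"))
    ref_len = length
    ref = rng.choice(bases, size=ref_len)
    anchor_ref_pos = anchor_column  # in ungapped reference coordinates for now
    for o in offsets:
        p = anchor_ref_pos + o
        if not 0 <= p < ref_len:
            raise ValueError(f"planted offset {o} falls outside the sequence")

    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    ing_ids = [f"h{i:02d}" for i in range(n_haplotypes)]
    seqs = {hid: ref.copy() for hid in ing_ids}
    truth = {"offsets": offsets, "alleles": {}, "carriers": {}}
    for o in offsets:
        p = anchor_ref_pos + o
        anc = ref[p]
        der = transitions[anc]
        n_carriers = max(1, min(n_haplotypes - 1, round(carrier_fraction * n_haplotypes)))
        carriers = rng.choice(n_haplotypes, size=n_carriers, replace=False)
        for ci in carriers:
            seqs[ing_ids[ci]][p] = der
        truth["alleles"][o] = (anc, der)
        truth["carriers"][o] = sorted(ing_ids[ci] for ci in carriers)

    cols = {hid: list(s) for hid, s in seqs.items()}
    out_cols = list(ref)
    # insert reference-gap columns (insertions private to one ingroup
    # haplotype) at random interior positions
    gap_positions = sorted(
        rng.choice(np.arange(1, ref_len), size=n_ref_gap_columns, replace=False), reverse=True
    )
    for gp in gap_positions:
        carrier = ing_ids[int(rng.integers(0, n_haplotypes))]
        for hid in ing_ids:
            cols[hid].insert(gp, str(rng.choice(bases)) if hid == carrier else "-")
        out_cols.insert(gp, "-")

    # recompute the anchor's alignment column after gap insertion
    anchor_aln_col = anchor_ref_pos + sum(1 for gp in gap_positions if gp <= anchor_ref_pos)

    sequences = {hid: "".join(c) for hid, c in cols.items()}
    sequences["outgroup"] = "".join(out_cols)
    if groups is None:
        groups = {hid: "pop" for hid in ing_ids}
    aln = AlignedHaplotypes(
        sequences=sequences,
        outgroup_id="outgroup",
        anchor_column=anchor_aln_col,
        groups=groups,
        founder={hid: True for hid in ing_ids},
        individual={hid: hid for hid in ing_ids},
    )
    truth["anchor_column"] = anchor_aln_col
    return aln, truth
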