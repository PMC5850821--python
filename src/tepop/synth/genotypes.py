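"""Synthetic SNV genotypes with population structure and planted QTL.

Strains are fully inbred (selfing hermaphrodite panel), so genotypes are
coded {0, 1} for the two homozygote classes.  Structure is generated
Balding–Nichols style: each subpopulation's allele frequency is drawn
around an ancestral frequency with divergence controlled by
``fst_like``.  Count traits are a baseline plus planted marker effects,
an optional structure term and Gaussian noise, discretized to
non-negative integers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MARKER_COLUMNS = ["marker", "chrom", "position"]


def simulate_snv_genotypes(
    n_strains: int,
    n_markers: int,
    n_subpops: int = 3,
    fst_like: float = 0.0,
    causal_spec: list[tuple[int, float, str]] | None = None,
    trait_noise_sd: float = 1.0,
    seed: int = 0,
    layout: pd.DataFrame | None = None,
    baseline: float = 20.0,
    structure_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Returns ``(genotypes, markers, traits, subpop_labels)``.

    ``genotypes``: strains x markers, values {0, 1}.  ``markers``: one
    row per marker with genome coordinates (spread over ``layout`` if
    given, else a single pseudo-chromosome).  ``traits``: strains x
    trait-name count table containing every trait named in
    ``causal_spec`` (plus ``"trait"`` if the spec is empty).
    """
    if causal_spec is None:
        causal_spec = []
    rng = np.random.default_rng(seed)
    strains = [f"ST{i:03d}" for i in range(n_strains)]
    marker_ids = [f"snv{i:05d}" for i in range(n_markers)]

    p_anc = rng.uniform(0.1, 0.9, size=n_markers)
    subpop = np.arange(n_strains) % n_subpops
    if fst_like > 0:
        f = fst_like
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p_sub = rng.beta(a[None, :], b[None, :], size=(n_subpops, n_markers))
    else:
        p_sub = np.tile(p_anc, (n_subpops, 1))
    G = (rng.random((n_strains, n_markers)) < p_sub[subpop]).astype(np.int8)
    genotypes = pd.DataFrame(G, index=strains, columns=marker_ids)

    if layout is not None:
        lengths = layout["length"].to_numpy(float)
        per_chrom = np.maximum(1, np.round(n_markers * lengths / lengths.sum()).astype(int))
        while per_chrom.sum() > n_markers:
            per_chrom[np.argmax(per_chrom)] -= 1
        while per_chrom.sum() < n_markers:
            per_chrom[np.argmax(lengths)] += 1
        rows, i = [], 0
        for (_, crow), k in zip(layout.iterrows(), per_chrom):
            pos = np.sort(rng.choice(np.arange(1, int(crow["length"]) + 1), size=k, replace=False))
            for p in pos:
                rows.append((marker_ids[i], str(crow["chrom"]), int(p)))
                i += 1
    else:
        rows = [(m, "chr1", 1000 * (i + 1)) for i, m in enumerate(marker_ids)]
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)

    trait_names = sorted({name for _, _, name in causal_spec}) or ["trait"]
    effects: dict[str, np.ndarray] = {t: np.zeros(n_strains) for t in trait_names}
    for marker_idx, effect, trait in causal_spec:
        g = G[:, marker_idx].astype(float)
        freq = g.mean()
        if freq in (0.0, 1.0):
            raise ValueError(f"causal marker {marker_idx} is monomorphic (MAF 0)")
        effects[trait] = effects[trait] + effect * g
    struct_shift = rng.normal(0, 1, size=n_subpops) if structure_sd > 0 else np.zeros(n_subpops)
    traits = {}
    for t in trait_names:
        raw = (
            baseline
            + effects[t]
            + structure_sd * struct_shift[subpop]
            + rng.normal(0, trait_noise_sd, size=n_strains)
        )
        traits[t] = np.maximum(0, np.round(raw)).astype(int)
    trait_table = pd.DataFrame(traits, index=strains)
    return genotypes, markers, trait_table, subpop


VARIANT_COLUMNS = ["variant_id", "gene", "gene_class", "chrom", "position", "effect",
                   "ref_aa", "alt_aa", "af"]

_AA = "ARNDCQEGHILKMFPSTWYV"


def make_variant_effects(
    markers: pd.DataFrame,
    genotypes: pd.DataFrame,
    n_variants: int,
    gene_pool: list[str] | None = None,
    gene_classes: dict[str, str] | None = None,
    effect_probs: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein-variant table tied to existing marker genotypes.

    Picks ``n_variants`` markers, assigns each a gene, a predicted
    effect severity and an amino-acid change, and reuses the marker's
    genotype column as the variant's strain genotypes (so allele
    frequencies and trait correlations are internally consistent).
    Returns ``(variants, variant_genotypes)``.
    """
    if effect_probs is None:
        effect_probs = {"low": 0.4, "moderate": 0.4, "severe": 0.2}
    rng = np.random.default_rng(seed)
    n_variants = min(n_variants, len(markers))
    pick = np.sort(rng.choice(len(markers), size=n_variants, replace=False))
    effects = list(effect_probs)
    eprobs = np.array([effect_probs[e] for e in effects])
    if gene_pool is None:
        gene_pool = [f"gene{i:04d}" for i in range(max(10, n_variants // 3))]
    rows = []
    geno_cols = {}
    for j, mi in enumerate(pick):
        m = markers.iloc[mi]
        vid = f"var{j:04d}"
        gene = str(rng.choice(gene_pool))
        ref, alt = rng.choice(list(_AA), size=2, replace=False)
        g = genotypes.iloc[:, mi]
        rows.append((vid, gene, (gene_classes or {}).get(gene, "te_control"),
                     m["chrom"], int(m["position"]), str(rng.choice(effects, p=eprobs)),
                     str(ref), str(alt), float(g.mean())))
        geno_cols[vid] = g.to_numpy()
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    vgeno = pd.DataFrame(geno_cols, index=genotypes.index)
    return variants, vgeno
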