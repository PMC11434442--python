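"""Synthetic community generator with planted correlation structure.

Counts follow a latent-factor lognormal-multinomial model: each planted
module has a per-sample standard-normal factor; member taxa add
loading * factor to their log-abundance, with residual normal noise scaled
so the latent variance stays 1 (latent pairwise correlation = loading^2).
Hub taxa get their own star factor with a strong hub loading and a weaker
partner loading, producing high-degree nodes whose partners are only weakly
interconnected. Per-sample counts are drawn multinomially at a lognormal
library size, giving compositional integer tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rhizonet.datasets import (
    AbundanceTable,
    SampleMetadata,
    TaxonomyTable,
)
from rhizonet.errors import ValidationError
from rhizonet.keystones import DEFAULT_CATEGORY_ENZYMES

STRATA = [
    ("wild", "unfertilized"),
    ("traditional", "unfertilized"),
    ("modern", "unfertilized"),
    ("wild", "fertilized"),
    ("traditional", "fertilized"),
    ("modern", "fertilized"),
]


def stratum_label(group: str, fertilization: str) -> str:
    return f"{group}_{fertilization}"


@dataclass(frozen=True)
class ModuleDesign:
    """A block of co-varying taxa, active in the listed strata."""

    size: int
    loading: float
    strata: tuple  # of stratum labels; empty = active everywhere

    def __post_init__(self):
        if self.size < 2:
            raise ValidationError("module size must be >= 2")
        if not (0.0 < self.loading <= 1.0):
            raise ValidationError("loading must be in (0, 1]")


@dataclass(frozen=True)
class HubDesign:
    """A star: one hub taxon strongly tied to each of n_partners taxa."""

    n_partners: int
    hub_loading: float = 0.97
    partner_loading: float = 0.80
    strata: tuple = ()

    def __post_init__(self):
        if self.n_partners < 1:
            raise ValidationError("hub needs >= 1 partner")
        for lo in (self.hub_loading, self.partner_loading):
            if not (0.0 < lo <= 1.0):
                raise ValidationError("loadings must be in (0, 1]")


@dataclass(frozen=True)
class SynthSpec:
    """Generative parameters for a synthetic community dataset."""

    n_taxa: int = 200
    n_phyla: int = 12
    samples_per_stratum: int = 40
    library_median: float = 30_000.0
    library_sigma: float = 0.25
    library_floor: int = 10_000
    baseline_sigma: float = 1.0
    structured_boost: float = 8.0
    latent_scale: float = 1.0
    modules: tuple = ()
    hubs: tuple = ()
    seed: int = 0

    def __post_init__(self):
        needed = sum(m.size for m in self.modules) + sum(
            1 + h.n_partners for h in self.hubs
        )
        if needed > self.n_taxa:
            raise ValidationError(
                f"planted structure needs {needed} taxa but n_taxa={self.n_taxa}"
            )


def preset_paper_like(loading: float = 0.95, seed: int = 0) -> SynthSpec:
    """Six-strata preset with a planted network-density gradient.

    Module counts per stratum are 3/5/7 (unfertilized wild/traditional/
    modern) and 8/4/6 (fertilized wild/traditional/modern), so edge counts
    rise along the domestication gradient without fertilizer while the wild
    group dominates with fertilizer.
    """
    uw, ut, um = "wild_unfertilized", "traditional_unfertilized", "modern_unfertilized"
    fw, ft, fm = "wild_fertilized", "traditional_fertilized", "modern_fertilized"
    activity = [
        (uw, ut, um, fw, ft, fm),
        (uw, ut, um, fw, ft, fm),
        (uw, ut, um, fw, ft, fm),
        (ut, um, fw, ft, fm),
        (ut, um, fw, fm),
        (um, fw, fm),
        (um, fw),
        (fw,),
    ]
    modules = tuple(ModuleDesign(size=10, loading=loading, strata=s) for s in activity)
    hubs = (
        HubDesign(n_partners=12, strata=()),
        HubDesign(n_partners=12, strata=()),
    )
    return SynthSpec(modules=modules, hubs=hubs, seed=seed)


def _assign_structure(spec: SynthSpec):
    """Allocate disjoint taxon index blocks to modules and hub stars."""
    cursor = 0
    module_taxa = []
    for m in spec.modules:
        module_taxa.append(list(range(cursor, cursor + m.size)))
        cursor += m.size
    hub_taxa = []
    for h in spec.hubs:
        hub = cursor
        partners = list(range(cursor + 1, cursor + 1 + h.n_partners))
        hub_taxa.append((hub, partners))
        cursor += 1 + h.n_partners
    return module_taxa, hub_taxa


def _active(design_strata: tuple, label: str) -> bool:
    return not design_strata or label in design_strata


def generate(spec: SynthSpec):
    """Generate the full synthetic dataset.

    Returns (AbundanceTable, TaxonomyTable, SampleMetadata, gene_presence
    DataFrame, ground-truth dict). Deterministic for a fixed spec/seed.
    """
    rng = np.random.default_rng(spec.seed)
    module_taxa, hub_taxa = _assign_structure(spec)

    taxon_ids = [f"t{i:04d}" for i in range(spec.n_taxa)]

    # taxonomy: Dirichlet-distributed phylum sizes over shuffled taxa
    phylum_names = [f"Phylum_{chr(ord('A') + i)}" for i in range(spec.n_phyla)]
    weights = rng.dirichlet(np.full(spec.n_phyla, 2.0))
    assignment = rng.choice(spec.n_phyla, size=spec.n_taxa, p=weights)
    taxonomy = TaxonomyTable(
        pd.DataFrame(
            {
                "phylum": [phylum_names[a] for a in assignment],
                "species": [f"Species {i:04d}" for i in range(spec.n_taxa)],
            },
            index=pd.Index(taxon_ids, name="taxon_id"),
        )
    )

    # baselines: lognormal over taxa, structured taxa boosted so planted
    # signal survives multinomial sampling
    log_base = rng.normal(0.0, spec.baseline_sigma, size=spec.n_taxa)
    structured = sorted(
        {i for block in module_taxa for i in block}
        | {h for h, _ in hub_taxa}
        | {p for _, ps in hub_taxa for p in ps}
    )
    log_base[structured] += np.log(spec.structured_boost)

    # residual noise scale per taxon per stratum keeps latent variance at 1
    sample_rows = []
    meta_rows = []
    count_blocks = []
    for group, fert in STRATA:
        label = stratum_label(group, fert)
        n = spec.samples_per_stratum
        loadings = np.zeros(spec.n_taxa)
        factor_members: list[tuple[np.ndarray, np.ndarray]] = []
        for m, block in zip(spec.modules, module_taxa):
            if _active(m.strata, label):
                lam = np.zeros(spec.n_taxa)
                lam[block] = m.loading
                factor_members.append((np.asarray(block), np.full(len(block), m.loading)))
                loadings[block] = m.loading
        for h, (hub, partners) in zip(spec.hubs, hub_taxa):
            if _active(h.strata, label):
                idx = np.asarray([hub] + partners)
                lam = np.concatenate([[h.hub_loading], np.full(len(partners), h.partner_loading)])
                factor_members.append((idx, lam))
                loadings[idx] = lam
        resid_scale = np.sqrt(np.clip(1.0 - loadings**2, 0.0, None))

        z = rng.normal(0.0, 1.0, size=(n, spec.n_taxa)) * resid_scale
        for idx, lam in factor_members:
            f = rng.normal(0.0, 1.0, size=n)
            z[:, idx] += np.outer(f, lam)

        log_abund = log_base + spec.latent_scale * z
        # softmax per sample -> compositional probabilities
        log_abund -= log_abund.max(axis=1, keepdims=True)
        probs = np.exp(log_abund)
        probs /= probs.sum(axis=1, keepdims=True)

        libs = np.maximum(
            spec.library_floor,
            np.round(
                rng.lognormal(np.log(spec.library_median), spec.library_sigma, size=n)
            ).astype(int),
        )
        counts = np.vstack(
            [rng.multinomial(libs[i], probs[i]) for i in range(n)]
        )
        count_blocks.append(counts)
        for i in range(n):
            sid = f"{label}_s{i:02d}"
            sample_rows.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "domestication_group": group,
                    "fertilization": fert,
                    "replicate": i,
                }
            )

    counts = pd.DataFrame(
        np.vstack(count_blocks),
        index=pd.Index(sample_rows, name="sample_id"),
        columns=taxon_ids,
    )
    table = AbundanceTable(counts)
    metadata = SampleMetadata(
        pd.DataFrame(meta_rows).set_index("sample_id")
    )

    gene_presence = _gene_presence(taxon_ids, hub_taxa, rng)
    truth = _ground_truth(spec, module_taxa, hub_taxa, taxon_ids)
    return table, taxonomy, metadata, gene_presence, truth


def _gene_presence(taxon_ids, hub_taxa, rng) -> pd.DataFrame:
    """Taxon x EC copy-number table; every category gets >= 3 carriers."""
    ecs = [ec for enzymes in DEFAULT_CATEGORY_ENZYMES.values() for _, ec in enzymes]
    n = len(taxon_ids)
    mat = (rng.random((n, len(ecs))) < 0.15).astype(int)
    mat *= rng.integers(1, 4, size=mat.shape)  # copy numbers 1-3 where present
    frame = pd.DataFrame(mat, index=pd.Index(taxon_ids, name="taxon_id"), columns=ecs)
    for category, enzymes in DEFAULT_CATEGORY_ENZYMES.items():
        cat_ecs = [ec for _, ec in enzymes]
        carriers = (frame[cat_ecs] >= 1).any(axis=1)
        deficit = 3 - int(carriers.sum())
        if deficit > 0:
            candidates = frame.index[~carriers]
            chosen = rng.choice(candidates, size=deficit, replace=False)
            frame.loc[chosen, cat_ecs[0]] = 1
    return frame


def _ground_truth(spec, module_taxa, hub_taxa, taxon_ids) -> dict:
    labels = [stratum_label(g, f) for g, f in STRATA]
    modules = []
    for m, block in zip(spec.modules, module_taxa):
        modules.append(
            {
                "taxa": [taxon_ids[i] for i in block],
                "loading": m.loading,
                "strata": list(m.strata) if m.strata else labels,
            }
        )
    hubs = []
    for h, (hub, partners) in zip(spec.hubs, hub_taxa):
        hubs.append(
            {
                "hub": taxon_ids[hub],
                "partners": [taxon_ids[p] for p in partners],
                "hub_loading": h.hub_loading,
                "partner_loading": h.partner_loading,
                "strata": list(h.strata) if h.strata else labels,
            }
        )
    modules_per_stratum = {
        lab: sum(1 for m in modules if lab in m["strata"]) for lab in labels
    }
    density_order = {
        fert: sorted(
            (g for g, f in STRATA if f == fert),
            key=lambda g: modules_per_stratum[stratum_label(g, fert)],
        )
        for fert in ("unfertilized", "fertilized")
    }
    within_pairs = {
        lab: [
            sorted((a, b))
            for m in modules
            if lab in m["strata"]
            for i, a in enumerate(m["taxa"])
            for b in m["taxa"][i + 1:]
        ]
        for lab in labels
    }
    return {
        "seed": spec.seed,
        "modules": modules,
        "hubs": hubs,
        "modules_per_stratum": modules_per_stratum,
        "density_order_ascending": density_order,
        "within_module_pairs": within_pairs,
    }


def write_dataset(out_dir, table, taxonomy, metadata, gene_presence, truth) -> None:
    """Write all generated tables plus the ground-truth JSON to a directory."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.counts.to_csv(out / "abundance.tsv", sep="\t")
    taxonomy.lineage.to_csv(out / "taxonomy.tsv", sep="\t")
    metadata.frame.to_csv(out / "metadata.tsv", sep="\t")
    gene_presence.to_csv(out / "gene_presence.tsv", sep="\t")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
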