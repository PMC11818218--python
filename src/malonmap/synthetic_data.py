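"""Ground-truth-labeled synthetic input bundles.

The generator emulates a 2-group (control vs salicylic-acid treatment),
replicate label-free PTM experiment: log-normal site intensities with
multiplicative replicate noise, completely-at-random missing values,
planted differential sites of known fold change, sites whose apparent
shift is entirely protein-abundance-driven (rescued by protein
correction), planted sequence motifs in the foreground windows, planted
enriched annotation terms among differential proteins, and a random
interaction graph with a planted hub. Every stage of the pipeline is
therefore testable against a known truth table without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    AA_ALPHABET,
    ProteinQuantTable,
    SiteIntensityTable,
    make_site_id,
    normalize_edges,
    write_annotation,
    write_edge_table,
    write_fasta,
    write_protein_table,
    write_site_table,
)


@dataclass(frozen=True)
class MotifSpec:
    """A planted motif: carriers get ``residue`` at ``offset`` from the
    modified lysine; the proteome-wide frequency of that residue is pinned
    at ``bg_frequency``."""

    offset: int = 2
    residue: str = "C"
    fg_carry_fraction: float = 0.6
    bg_frequency: float = 0.02


@dataclass(frozen=True)
class EnrichedTermSpec:
    """A planted annotation enrichment among differential proteins."""

    namespace: str = "KEGG"
    term_id: str = "ko00620"
    term_name: str = "Pyruvate metabolism"
    carry_fraction_in_diff: float = 0.8
    background_fraction: float = 0.1


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults mirror the emulated design: 2 groups x 2 replicates, 2000
    modification sites over 300 proteins, planted fold changes drawn from
    [2, 4] (reciprocals for down-regulation), replicate noise of 0.05 on
    the log2 scale, 5% missing cells.
    """

    seed: int = 0
    n_proteins: int = 300
    n_sites: int = 2000
    n_samples_per_group: int = 2
    group_control: str = "C"
    group_treatment: str = "SA"
    frac_differential: float = 0.05
    frac_up: float = 0.5  # share of differential sites that are up-regulated
    true_fc_range: tuple[float, float] = (2.0, 4.0)
    replicate_noise_sigma_log2: float = 0.05
    protein_noise_sigma_log2: float = 0.0
    missing_rate: float = 0.05
    protein_confounding: float = 0.1
    k_frequency: float = 0.07
    seq_length_range: tuple[int, int] = (150, 600)
    baseline_log10_mu: float = 7.0  # log10 of ~1e7 median intensity
    baseline_log10_sigma: float = 0.5
    motif_spec: list[MotifSpec] = field(default_factory=lambda: [MotifSpec()])
    enriched_terms: list[EnrichedTermSpec] = field(
        default_factory=lambda: [EnrichedTermSpec()]
    )
    n_random_terms: int = 30
    edge_density: float = 0.02
    hub_degree: int = 15

    def validate(self) -> None:
        for name in ("frac_differential", "frac_up", "missing_rate",
                     "protein_confounding", "k_frequency"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.k_frequency <= 0:
            raise ValueError("alphabet must generate lysines (k_frequency > 0)")
        if self.true_fc_range[0] <= 1:
            raise ValueError("true_fc_range must lie above 1")
        for m in self.motif_spec:
            if m.offset == 0 or abs(m.offset) > 10:
                raise ValueError("motif offset must be in [-10, 10] and nonzero")
            if m.residue not in AA_ALPHABET:
                raise ValueError(f"unknown motif residue {m.residue!r}")


@dataclass
class SimulationBundle:
    """In-memory result of one simulation."""

    site_table: SiteIntensityTable
    protein_table: ProteinQuantTable
    fasta_map: dict[str, str]
    annotations: pd.DataFrame
    edges: pd.DataFrame
    truth_sites: pd.DataFrame  # indexed by site_id
    truth_proteins: pd.DataFrame  # indexed by protein_id
    config: SimulationConfig


def _residue_probs(config: SimulationConfig) -> np.ndarray:
    """Per-letter generation probabilities honoring pinned frequencies."""
    pinned = {"K": config.k_frequency}
    for m in config.motif_spec:
        pinned.setdefault(m.residue, m.bg_frequency)
    free = [aa for aa in AA_ALPHABET if aa not in pinned]
    rest = 1.0 - sum(pinned.values())
    if rest <= 0:
        raise ValueError("pinned residue frequencies exceed 1")
    probs = np.array(
        [pinned.get(aa, rest / len(free)) for aa in AA_ALPHABET]
    )
    return probs / probs.sum()


def simulate(config: SimulationConfig) -> SimulationBundle:
    """Generate a full input bundle plus its truth tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(AA_ALPHABET))
    probs = _residue_probs(config)

    # --- protein sequences --------------------------------------------------
    n_prot = config.n_proteins
    width = len(str(n_prot))
    protein_ids = [f"PGR_{i + 1:0{width}d}" for i in range(n_prot)]
    seqs: dict[str, np.ndarray] = {}
    for pid in protein_ids:
        length = int(rng.integers(config.seq_length_range[0],
                                  config.seq_length_range[1] + 1))
        seq = rng.choice(aa, size=length, p=probs)
        if not (seq == "K").any():
            seq[int(rng.integers(length))] = "K"
        seqs[pid] = seq

    # --- choose modification sites at lysines ------------------------------
    all_k = [(pid, i + 1) for pid in protein_ids
             for i in np.flatnonzero(seqs[pid] == "K")]
    n_sites = min(config.n_sites, len(all_k))
    chosen_idx = np.sort(rng.choice(len(all_k), size=n_sites, replace=False))
    sites = [all_k[i] for i in chosen_idx]
    site_positions = {pid: set() for pid in protein_ids}
    for pid, pos in sites:
        site_positions[pid].add(pos)

    # --- plant regulation truth --------------------------------------------
    n_diff = int(round(config.frac_differential * n_sites))
    n_conf = int(round(config.protein_confounding * n_sites))
    perm = rng.permutation(n_sites)
    diff_idx = perm[:n_diff]
    conf_idx = perm[n_diff : n_diff + n_conf]  # confounded sites are non-diff

    lo, hi = config.true_fc_range
    true_fc = np.ones(n_sites)  # modification-level (post-correction) truth
    n_up = int(round(config.frac_up * n_diff))
    for rank, i in enumerate(diff_idx):
        mag = rng.uniform(lo, hi)
        true_fc[i] = mag if rank < n_up else 1.0 / mag

    protein_fc = {pid: 1.0 for pid in protein_ids}
    conf_apparent = np.ones(n_sites)
    for rank, i in enumerate(conf_idx):
        mag = rng.uniform(lo, hi)
        fc = mag if rank % 2 == 0 else 1.0 / mag
        pid = sites[i][0]
        if protein_fc[pid] == 1.0:
            protein_fc[pid] = fc
        conf_apparent[i] = protein_fc[pid]

    # --- plant sequence motifs ---------------------------------------------
    # only chosen site centers are protected from overwriting, so the
    # residual (non-carrier) foreground keeps the background composition
    motif_carrier = np.zeros(n_sites, dtype=bool)
    for m in config.motif_spec:
        carry = rng.random(n_sites) < m.fg_carry_fraction
        for i in np.flatnonzero(carry):
            pid, pos = sites[i]
            target = pos - 1 + m.offset
            seq = seqs[pid]
            if 0 <= target < len(seq) and (target + 1) not in site_positions[pid]:
                seq[target] = m.residue
                motif_carrier[i] = True

    fasta_map = {pid: "".join(seqs[pid]) for pid in protein_ids}

    # --- intensities --------------------------------------------------------
    n_rep = config.n_samples_per_group
    control = [f"{config.group_control}{r + 1}" for r in range(n_rep)]
    treated = [f"{config.group_treatment}{r + 1}" for r in range(n_rep)]
    samples = control + treated
    groups = {s: config.group_control for s in control}
    groups.update({s: config.group_treatment for s in treated})

    # control replicates sit at the baseline; the treatment group carries
    # the planted fold change times multiplicative replicate noise
    sigma = config.replicate_noise_sigma_log2
    base = 10 ** rng.normal(config.baseline_log10_mu,
                            config.baseline_log10_sigma, n_sites)
    parent_fc = np.array([protein_fc[pid] for pid, _ in sites])
    raw_fc = true_fc * parent_fc  # apparent fold change in raw intensities
    noise = 2 ** rng.normal(0.0, sigma, size=(n_sites, n_rep))
    inten = np.empty((n_sites, 2 * n_rep))
    inten[:, :n_rep] = base[:, None]
    inten[:, n_rep:] = (base * raw_fc)[:, None] * noise
    if config.missing_rate > 0:
        inten[rng.random(inten.shape) < config.missing_rate] = np.nan

    site_ids = [make_site_id(pid, "K", pos) for pid, pos in sites]
    site_meta = pd.DataFrame(
        {
            "protein_id": [pid for pid, _ in sites],
            "position": [pos for _, pos in sites],
            "residue": "K",
            "localization_prob": np.round(rng.uniform(0.75, 1.0, n_sites), 4),
        },
        index=pd.Index(site_ids, name="site_id"),
    )
    site_table = SiteIntensityTable(
        sites=site_meta,
        intensities=pd.DataFrame(inten, index=site_meta.index, columns=samples),
        sample_groups=groups,
    )

    prot_base = 10 ** rng.normal(config.baseline_log10_mu + 0.3,
                                 config.baseline_log10_sigma, n_prot)
    prot_noise = 2 ** rng.normal(0.0, config.protein_noise_sigma_log2,
                                 size=(n_prot, n_rep))
    prot_fc_arr = np.array([protein_fc[pid] for pid in protein_ids])
    prot = np.empty((n_prot, 2 * n_rep))
    prot[:, :n_rep] = prot_base[:, None]
    prot[:, n_rep:] = (prot_base * prot_fc_arr)[:, None] * prot_noise
    protein_table = ProteinQuantTable(
        intensities=pd.DataFrame(
            prot, index=pd.Index(protein_ids, name="protein_id"), columns=samples
        )
    )

    # --- truth tables -------------------------------------------------------
    regulation = np.where(true_fc > 1.5, "UP",
                          np.where(true_fc < 1 / 1.5, "DOWN", "NS"))
    truth_sites = pd.DataFrame(
        {
            "protein_id": site_meta["protein_id"],
            "position": site_meta["position"],
            "true_fc": true_fc,
            "true_regulation": regulation,
            "confounded": np.isin(np.arange(n_sites), conf_idx),
            "apparent_fc": raw_fc,
            "motif_carrier": motif_carrier,
        },
        index=site_meta.index,
    )
    diff_proteins = sorted(set(truth_sites.loc[
        truth_sites["true_regulation"] != "NS", "protein_id"]))
    truth_proteins = pd.DataFrame(
        {
            "true_protein_fc": prot_fc_arr,
            "is_differential": [pid in set(diff_proteins) for pid in protein_ids],
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )

    # --- annotations --------------------------------------------------------
    ann_rows = []
    diff_set = set(diff_proteins)
    for spec in config.enriched_terms:
        draw = rng.random(n_prot)
        for j, pid in enumerate(protein_ids):
            p_carry = (spec.carry_fraction_in_diff if pid in diff_set
                       else spec.background_fraction)
            if draw[j] < p_carry:
                ann_rows.append((pid, spec.namespace, spec.term_id, spec.term_name))
    namespaces = ["GO-BP", "GO-CC", "GO-MF", "KEGG", "DOMAIN", "COMPARTMENT"]
    for t in range(config.n_random_terms):
        ns = namespaces[t % len(namespaces)]
        term_id = f"{ns}:{t + 1:04d}"
        p_carry = rng.uniform(0.02, 0.15)
        draw = rng.random(n_prot)
        for j, pid in enumerate(protein_ids):
            if draw[j] < p_carry:
                ann_rows.append((pid, ns, term_id, f"random term {t + 1}"))
    annotations = pd.DataFrame(
        ann_rows, columns=["protein_id", "namespace", "term_id", "term_name"]
    )

    # --- interaction edges --------------------------------------------------
    edge_rows = []
    iu, ju = np.triu_indices(n_prot, k=1)
    pick = rng.random(len(iu)) < config.edge_density
    scores = rng.random(len(iu))
    for a, b, s in zip(iu[pick], ju[pick], scores[pick]):
        edge_rows.append((protein_ids[a], protein_ids[b], s))
    if diff_proteins:
        hub = diff_proteins[0]
        partners = [p for p in diff_proteins if p != hub][: config.hub_degree]
        for p in partners:
            edge_rows.append((hub, p, float(rng.uniform(0.75, 1.0))))
    edges = normalize_edges(
        pd.DataFrame(edge_rows, columns=["protein_a", "protein_b", "score"])
    )

    return SimulationBundle(
        site_table=site_table,
        protein_table=protein_table,
        fasta_map=fasta_map,
        annotations=annotations,
        edges=edges,
        truth_sites=truth_sites,
        truth_proteins=truth_proteins,
        config=config,
    )


def write_bundle(bundle: SimulationBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle in the exact dialects the loaders read.

    Returns a name -> path map. Output is byte-identical for a fixed
    config (all randomness flows from the config seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": out / "sites.tsv",
        "proteins": out / "proteins.tsv",
        "fasta": out / "proteins.fasta",
        "annotations": out / "annotations.tsv",
        "edges": out / "edges.tsv",
        "truth_sites": out / "truth_sites.tsv",
        "truth_proteins": out / "truth_proteins.tsv",
        "groups": out / "groups.yaml",
    }
    write_site_table(bundle.site_table, paths["sites"])
    write_protein_table(bundle.protein_table, paths["proteins"])
    write_fasta(bundle.fasta_map, paths["fasta"])
    write_annotation(bundle.annotations, paths["annotations"])
    write_edge_table(bundle.edges, paths["edges"])
    bundle.truth_sites.to_csv(paths["truth_sites"], sep="\t",
                              float_format="%.10g")
    bundle.truth_proteins.to_csv(paths["truth_proteins"], sep="\t",
                                 float_format="%.10g")
    with open(paths["groups"], "w") as fh:
        yaml.safe_dump({"sample_groups": bundle.site_table.sample_groups}, fh,
                       sort_keys=True)
    return paths
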