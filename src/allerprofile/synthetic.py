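"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate the study design of a six-crab-species allergen
comparison: five closely related true crabs (CF, PP, SP, CO, ES) and a king
crab (PC) outgroup.  The default species tree is ultrametric with topology
``((((CF,PP),SP),(CO,ES)),PC)`` and the PC branch far longer than the
in-group branches, so every generator inherits the outgroup signal that the
downstream analyses are expected to recover:

* band profiles evolve by per-branch Bernoulli presence flips, so band-sharing
  similarity decays with path length on the tree;
* protein families evolve by per-site Poisson substitution with epitope
  columns substituting at a fraction (default 1/5) of the background rate;
* OD plates draw lognormal negative and positive sera around a configurable
  true-positive fraction over the 3x-negative-mean cutoff;
* inhibition series follow a Hill curve with multiplicative noise;
* TPM tables are lognormal with one dominant tropomyosin-like transcript and
  a hemocyanin-like allergen that is near-absent in muscle tissue.

Every generator is deterministic given its seed and returns ground truth
alongside the data so recovery tests are self-contained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .band_profiles import BandProfileMatrix
from .conservation import AMINO_ACIDS, AlignmentBlock, EpitopeRegion
from .expression import ExpressionTable
from .serology import InhibitionSeries, ODPlate
from .trees import Node, leaf

__all__ = [
    "SPECIES",
    "ALLERGENS",
    "default_species_tree",
    "SimulationConfig",
    "gen_band_profiles",
    "gen_protein_family",
    "gen_od_plate",
    "gen_inhibition_series",
    "gen_tpm",
    "write_band_calls",
    "write_alignment_fasta",
    "write_epitope_table",
    "write_plate",
    "write_inhibition",
    "write_quant_tree",
    "generate_all",
]

SPECIES = ["CF", "PP", "SP", "CO", "ES", "PC"]

# 11 putative allergen groups under comparison
ALLERGENS = ["TM", "AK", "FLNC", "PM", "MHC", "GP", "HC", "HSP", "ALD", "PGM", "MDH"]

MIXED_TISSUE_SPECIES = ("PP", "CO")


def default_species_tree() -> Node:
    """Ultrametric six-leaf tree ((((CF,PP),SP),(CO,ES)),PC), PC the outgroup.

    Node heights are divergence depths in arbitrary time units.  The king-crab
    split sits at depth 8, far above the in-group structure (depths 0.5-5),
    and the internal branches are long relative to the terminal ones so the
    generating topology is identifiable from finite band/sequence data.
    """
    cf_pp = Node(height=0.5, children=(leaf("CF"), leaf("PP")))
    cfpp_sp = Node(height=2.5, children=(cf_pp, leaf("SP")))
    co_es = Node(height=1.0, children=(leaf("CO"), leaf("ES")))
    ingroup = Node(height=5.0, children=(cfpp_sp, co_es))
    return Node(height=8.0, children=(ingroup, leaf("PC")))


def _branch_lengths(tree: Node):
    """Yield (child, branch_length) pairs in pre-order."""
    for node in tree.iter_nodes():
        for child in node.children:
            length = node.height - child.height
            if length <= 0:
                raise ValueError("tree heights must decrease toward the leaves")
            yield node, child, length


def _evolve_on_tree(tree: Node, root_state, mutate, rng) -> dict[str, object]:
    """Generic tree traversal: apply ``mutate(state, branch_length, rng)`` per branch."""
    states = {id(tree): root_state}
    out: dict[str, object] = {}
    for parent, child, length in _branch_lengths(tree):
        state = mutate(states[id(parent)], length, rng)
        states[id(child)] = state
        if child.is_leaf:
            out[child.label or ""] = state
    if tree.is_leaf:
        out[tree.label or ""] = root_state
    return out


def gen_band_profiles(
    tree: Node | None = None,
    n_bands: int = 150,
    flip_prob: float = 0.05,
    seed: int = 0,
    root_presence: float = 0.7,
) -> BandProfileMatrix:
    """Simulate band presence/absence profiles on a species tree.

    The root profile is Bernoulli(``root_presence``) per band; along each
    branch every band flips state independently with probability
    ``flip_prob x branch_length``, capped at 0.5 — the decorrelation limit of
    a symmetric two-state flip process, so saturated branches randomize the
    profile rather than inverting it.  Band labels carry molecular
    weights spaced log-evenly over 10-250 kDa, mirroring a typical gel range.
    The default 150 scoreable band positions represent the pooled annotation
    grid across gel and blot images rather than a single lane.
    """
    if not (0.0 <= flip_prob <= 1.0):
        raise ValueError("flip_prob must be a probability in [0, 1]")
    if not (0.0 <= root_presence <= 1.0):
        raise ValueError("root_presence must be a probability in [0, 1]")
    if n_bands < 10:
        raise ValueError("need at least 10 bands for a meaningful profile")
    tree = tree or default_species_tree()
    rng = np.random.default_rng(seed)
    root = (rng.random(n_bands) < root_presence).astype(np.int8)

    def mutate(profile, length, rng):
        p = min(0.5, flip_prob * length)
        flips = rng.random(n_bands) < p
        return np.where(flips, 1 - profile, profile).astype(np.int8)

    leaf_profiles = _evolve_on_tree(tree, root, mutate, rng)
    order = [lab for lab in SPECIES if lab in leaf_profiles] or sorted(leaf_profiles)
    order += [lab for lab in leaf_profiles if lab not in order]
    calls = np.vstack([leaf_profiles[lab] for lab in order])
    mw = np.round(np.geomspace(250.0, 10.0, n_bands), 1)
    labels = [f"B{i + 1:03d}" for i in range(n_bands)]
    return BandProfileMatrix(order, labels, mw, calls)


def gen_protein_family(
    tree: Node | None = None,
    length: int = 300,
    base_rate: float = 0.03,
    epitope_regions: Sequence[tuple[int, int]] = ((40, 60), (150, 175), (230, 250)),
    epitope_rate_multiplier: float = 0.2,
    seed: int = 0,
    gap_events: int = 0,
) -> AlignmentBlock:
    """Simulate a gapless homolog family with conserved epitope blocks.

    Per branch and site, the substitution count is Poisson with mean
    ``rate x branch_length`` where the rate is ``base_rate`` outside and
    ``base_rate x epitope_rate_multiplier`` inside the (1-based, inclusive)
    epitope intervals; each substitution replaces the residue uniformly with
    one of the other 19 amino acids.  ``gap_events`` > 0 additionally deletes
    short segments from random non-reference rows (residues replaced by '-'),
    purely to exercise downstream gap handling.
    """
    if not (0.0 < epitope_rate_multiplier <= 1.0):
        raise ValueError("epitope_rate_multiplier must be in (0, 1]")
    if base_rate < 0:
        raise ValueError("base_rate must be non-negative")
    spans = sorted(epitope_regions)
    covered: set[int] = set()
    for start, end in spans:
        if not (1 <= start <= end <= length):
            raise ValueError(f"epitope region ({start}, {end}) outside 1..{length}")
        sites = set(range(start - 1, end))
        if covered & sites:
            raise ValueError("epitope regions must not overlap")
        covered |= sites

    tree = tree or default_species_tree()
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    root = rng.choice(aa, size=length)
    site_rate = np.full(length, base_rate)
    site_rate[sorted(covered)] *= epitope_rate_multiplier

    def mutate(seq, branch_length, rng):
        seq = seq.copy()
        n_subs = rng.poisson(site_rate * branch_length)
        for site in np.nonzero(n_subs)[0]:
            for _ in range(int(n_subs[site])):
                choices = aa[aa != seq[site]]
                seq[site] = rng.choice(choices)
        return seq

    leaf_seqs = _evolve_on_tree(tree, root, mutate, rng)
    order = [lab for lab in SPECIES if lab in leaf_seqs] or sorted(leaf_seqs)
    rows = [leaf_seqs[lab].tobytes().decode() for lab in order]

    for _ in range(gap_events):
        i = int(rng.integers(1, len(rows)))  # never the first (reference) row
        start = int(rng.integers(0, length - 5))
        width = int(rng.integers(2, 6))
        row = rows[i]
        rows[i] = row[:start] + "-" * width + row[start + width:]
    return AlignmentBlock(order, rows)


def gen_od_plate(
    n_allergic: int = 50,
    n_negative: int = 3,
    true_positive_fraction: float = 0.14,
    neg_mean: float = 0.02,
    pos_fold: float = 20.0,
    cv: float = 0.2,
    seed: int = 0,
    antigen: str = "rMDH",
) -> tuple[ODPlate, dict]:
    """Simulate an ELISA plate with known sensitization ground truth.

    Negative-control and non-sensitized allergic sera draw OD450 from a
    lognormal with mean ``neg_mean`` and coefficient of variation ``cv``;
    sensitized sera draw from the same shape around ``pos_fold x neg_mean``.
    ``pos_fold`` must exceed the cutoff multiplier 3 so true positives clear
    the 3x-negative-mean cutoff in expectation.  The sensitized count is
    ``ceil(true_positive_fraction x n_allergic)``.
    """
    if n_allergic < 1 or n_negative < 1:
        raise ValueError("need at least one allergic and one nonallergic serum")
    if not (0.0 <= true_positive_fraction <= 1.0):
        raise ValueError("true_positive_fraction must be in [0, 1]")
    if pos_fold <= 3.0:
        raise ValueError("pos_fold must exceed 3 (the cutoff multiplier)")
    rng = np.random.default_rng(seed)

    def lognormal(mean: float, size: int) -> np.ndarray:
        if cv == 0.0:
            return np.full(size, mean)
        sigma2 = np.log1p(cv**2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size)

    # round before ceil so fractions like 0.14 x 50 = 7.000...01 stay exact
    n_pos = int(np.ceil(np.round(true_positive_fraction * n_allergic, 9)))
    sensitized = np.zeros(n_allergic, dtype=bool)
    sensitized[rng.choice(n_allergic, size=n_pos, replace=False)] = True
    ods = np.where(
        sensitized,
        lognormal(pos_fold * neg_mean, n_allergic),
        lognormal(neg_mean, n_allergic),
    )
    neg_ods = lognormal(neg_mean, n_negative)

    rows = []
    truth = {}
    for i in range(n_allergic):
        sid = f"A{i + 1:02d}"
        rows.append((sid, "allergic", antigen, float(ods[i])))
        truth[sid] = bool(sensitized[i])
    for i in range(n_negative):
        sid = f"N{i + 1:02d}"
        rows.append((sid, "nonallergic", antigen, float(neg_ods[i])))
        truth[sid] = False
    plate = ODPlate(pd.DataFrame(rows, columns=["serum_id", "status", "antigen", "od"]))
    ground_truth = {
        "sensitized": truth,
        "true_positive_fraction": true_positive_fraction,
        "n_sensitized": n_pos,
        "neg_mean": neg_mean,
        "pos_fold": pos_fold,
        "cv": cv,
    }
    return plate, ground_truth


DEFAULT_CONCENTRATIONS = tuple(float(c) for c in np.logspace(-4, 2, 7))


def gen_inhibition_series(
    Imax: float = 93.0,
    IC50: float = 0.1,
    hill: float = 1.0,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    od0: float = 1.0,
    cv: float = 0.05,
    seed: int = 0,
    inhibitor: str = "PC-MDH",
) -> tuple[InhibitionSeries, dict]:
    """Simulate a Hill-shaped inhibition dilution series.

    True inhibition at concentration c is ``Imax c^h / (IC50^h + c^h)``;
    measured signals are ``od0 (1 - inhibition/100)`` times multiplicative
    lognormal noise of coefficient of variation ``cv`` (the no-inhibitor well
    included).  The default span 1e-4..100 ug/mL matches a standard
    seven-point serial dilution.
    """
    if not (0.0 <= Imax <= 100.0):
        raise ValueError("Imax must be a percent in [0, 100]")
    if IC50 <= 0 or hill <= 0 or od0 <= 0:
        raise ValueError("IC50, hill and od0 must be positive")
    conc = np.asarray(list(concentrations), dtype=float)
    rng = np.random.default_rng(seed)
    inhibition = Imax * conc**hill / (IC50**hill + conc**hill)

    def noise(size: int) -> np.ndarray:
        if cv == 0.0:
            return np.ones(size)
        sigma2 = np.log1p(cv**2)
        return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size)

    signals = od0 * (1.0 - inhibition / 100.0) * noise(conc.size)
    s_no = float(od0 * noise(1)[0])
    series = InhibitionSeries(inhibitor, conc, signals, s_no)
    truth = {"Imax": Imax, "IC50": IC50, "hill": hill, "od0": od0, "cv": cv}
    return series, truth


def _default_allergen_means() -> dict[str, float]:
    # muscle-tissue TPM means, tropomyosin dominant (~2^19 relative units),
    # hemocyanin near-absent in muscle
    return {
        "TM": 524288.0,
        "PM": 60000.0,
        "MHC": 90000.0,
        "AK": 30000.0,
        "FLNC": 9000.0,
        "GP": 4000.0,
        "HSP": 700.0,
        "ALD": 2000.0,
        "PGM": 900.0,
        "MDH": 800.0,
        "HC": 5.0,
    }


def _default_samples_per_species() -> dict[str, int]:
    # mirrors the study's RNA-seq sample layout: one run each for CF/PP/CO,
    # four for SP, six for ES, three for PC
    return {"CF": 1, "PP": 1, "SP": 4, "CO": 1, "ES": 6, "PC": 3}


def gen_tpm(
    allergen_means: Mapping[str, float] | None = None,
    n_samples_per_species: Mapping[str, int] | None = None,
    dispersion: float = 0.5,
    seed: int = 0,
    isoforms: Mapping[str, int] | None = None,
    mixed_tissue_overrides: Mapping[str, float] | None = None,
    n_background: int = 50,
    background_mean: float = 200.0,
) -> tuple[ExpressionTable, dict]:
    """Simulate a transcript x sample TPM table with allergen annotations.

    Each allergen gets one or more isoform transcripts per species whose TPMs
    are lognormal around the allergen mean (split evenly across isoforms,
    lognormal sigma = ``dispersion``); ``n_background`` unmapped transcripts
    model the rest of the transcriptome.  Samples from mixed-tissue species
    (PP, CO) are labelled ``tissue="mixed"`` and take the hemocyanin-like
    override mean, reproducing the migrant-protein pattern where HC is high
    only outside muscle.  Every sample is renormalized to sum to 1e6 TPM.
    """
    means = dict(allergen_means or _default_allergen_means())
    if any(v < 0 for v in means.values()):
        raise ValueError("allergen means must be non-negative")
    per_species = dict(n_samples_per_species or _default_samples_per_species())
    isoforms = dict(isoforms or {"TM": 3, "PM": 2, "MHC": 2})
    overrides = dict(
        mixed_tissue_overrides if mixed_tissue_overrides is not None else {"HC": 30000.0}
    )
    rng = np.random.default_rng(seed)

    def draw(mean: float, size: int) -> np.ndarray:
        if mean == 0.0:
            return np.zeros(size)
        if dispersion == 0.0:
            return np.full(size, mean)
        return rng.lognormal(np.log(mean) - dispersion**2 / 2.0, dispersion, size)

    sample_rows = []
    for sp in SPECIES:
        for k in range(per_species.get(sp, 0)):
            tissue = "mixed" if sp in MIXED_TISSUE_SPECIES else "muscle"
            sample_rows.append((f"{sp}_{k + 1}", sp, tissue))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "species", "tissue"])

    mapping_rows = []
    tpm: dict[str, np.ndarray] = {}
    transcript_ids: list[str] = []
    for sp in SPECIES:
        if per_species.get(sp, 0) == 0:
            continue
        for allergen in ALLERGENS:
            for iso in range(isoforms.get(allergen, 1)):
                tx = f"{sp}_{allergen}_t{iso + 1}"
                transcript_ids.append(tx)
                mapping_rows.append((tx, allergen, sp))
        for b in range(n_background):
            transcript_ids.append(f"{sp}_bg_t{b + 1}")
    mapping = pd.DataFrame(mapping_rows, columns=["transcript_id", "allergen", "species"])

    data = pd.DataFrame(0.0, index=transcript_ids, columns=samples["sample_id"])
    for _, sample in samples.iterrows():
        sp, sid, tissue = sample["species"], sample["sample_id"], sample["tissue"]
        for allergen in ALLERGENS:
            mean = means[allergen]
            if tissue == "mixed" and allergen in overrides:
                mean = overrides[allergen]
            n_iso = isoforms.get(allergen, 1)
            values = draw(mean / n_iso, n_iso)
            for iso in range(n_iso):
                data.loc[f"{sp}_{allergen}_t{iso + 1}", sid] = values[iso]
        bg = draw(background_mean, n_background)
        for b in range(n_background):
            data.loc[f"{sp}_bg_t{b + 1}", sid] = bg[b]
        data[sid] *= 1e6 / data[sid].sum()

    table = ExpressionTable(data, mapping, samples)
    truth = {
        "allergen_means": means,
        "mixed_tissue_overrides": overrides,
        "dispersion": dispersion,
        "dominant_allergen": max(means, key=lambda a: means[a]),
    }
    return table, truth


# ---------------------------------------------------------------------------
# file emitters (plain-text fixtures for the CLI and pipeline)

def write_band_calls(m: BandProfileMatrix, path) -> None:
    rows = []
    for i, sp in enumerate(m.species_ids):
        for j, band in enumerate(m.band_labels):
            rows.append((sp, band, m.mw_kda[j], "+" if m.calls[i, j] else "-"))
    pd.DataFrame(rows, columns=["species", "band_label", "mw_kda", "present"]).to_csv(
        path, sep="\t", index=False
    )


def write_alignment_fasta(a: AlignmentBlock, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(a.seq_ids, a.rows):
            fh.write(f">{sid}\n{row}\n")


def write_epitope_table(
    a: AlignmentBlock,
    regions: Sequence[tuple[int, int]],
    path,
    allergen: str = "SYN",
    reference_id: str | None = None,
) -> list[EpitopeRegion]:
    """Emit an epitope TSV whose peptides are read off the reference row."""
    reference_id = reference_id or a.seq_ids[0]
    ref = a.row(reference_id).replace("-", "")
    epitopes = [
        EpitopeRegion(allergen, f"{allergen}_E{i + 1}", reference_id, s, e, ref[s - 1:e])
        for i, (s, e) in enumerate(regions)
    ]
    pd.DataFrame(
        [
            (e.allergen, e.epitope_id, e.reference_id, e.start, e.end, e.peptide)
            for e in epitopes
        ],
        columns=["allergen", "epitope_id", "reference_id", "start", "end", "peptide"],
    ).to_csv(path, sep="\t", index=False)
    return epitopes


def write_plate(plate: ODPlate, path) -> None:
    plate.data.to_csv(path, sep="\t", index=False)


def write_inhibition(series_list: Sequence[InhibitionSeries], path) -> None:
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "inhibitor": s.inhibitor,
                    "concentration_ug_ml": np.concatenate(([0.0], s.concentrations)),
                    "signal": np.concatenate(([s.signal_no_inhibitor], s.signals)),
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def write_quant_tree(table: ExpressionTable, out_dir) -> dict[str, Path]:
    """Write one Salmon-layout quant.sf per sample under ``out_dir/<sample>/``."""
    out_dir = Path(out_dir)
    paths = {}
    lengths = 500 + 17 * np.arange(len(table.tpm.index))
    for sid in table.tpm.columns:
        sample_dir = out_dir / str(sid)
        sample_dir.mkdir(parents=True, exist_ok=True)
        eff = np.maximum(lengths - 200, 1)
        tpm = table.tpm[sid].to_numpy()
        df = pd.DataFrame(
            {
                "Name": table.tpm.index,
                "Length": lengths,
                "EffectiveLength": eff.astype(float),
                "TPM": tpm,
                "NumReads": np.round(tpm * eff / 1000.0, 3),
            }
        )
        path = sample_dir / "quant.sf"
        df.to_csv(path, sep="\t", index=False)
        paths[str(sid)] = path
    return paths


@dataclass
class SimulationConfig:
    """Bundle of per-generator parameters for a full synthetic study."""

    seed: int = 0
    n_bands: int = 150
    flip_prob: float = 0.05
    protein_length: int = 300
    base_rate: float = 0.03
    epitope_regions: tuple[tuple[int, int], ...] = ((40, 60), (150, 175), (230, 250))
    epitope_rate_multiplier: float = 0.2
    n_allergic: int = 50
    n_negative: int = 3
    true_positive_fraction: float = 0.14
    neg_mean: float = 0.02
    pos_fold: float = 20.0
    od_cv: float = 0.2
    imax: float = 93.0
    ic50: float = 0.1
    hill: float = 1.0
    inhibition_cv: float = 0.05
    tpm_dispersion: float = 0.5

    def __post_init__(self) -> None:
        for name in ("flip_prob", "true_positive_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1]")


def generate_all(out_dir, config: SimulationConfig | None = None) -> dict:
    """Write a full synthetic study (all input files + ground truth) to a directory."""
    cfg = config or SimulationConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed

    bands = gen_band_profiles(
        n_bands=cfg.n_bands, flip_prob=cfg.flip_prob, seed=seed
    )
    write_band_calls(bands, out / "band_calls.tsv")

    family = gen_protein_family(
        length=cfg.protein_length,
        base_rate=cfg.base_rate,
        epitope_regions=cfg.epitope_regions,
        epitope_rate_multiplier=cfg.epitope_rate_multiplier,
        seed=seed + 1,
    )
    write_alignment_fasta(family, out / "alignment.fasta")
    write_epitope_table(
        family, cfg.epitope_regions, out / "epitopes.tsv", reference_id="SP"
    )

    plate, plate_truth = gen_od_plate(
        n_allergic=cfg.n_allergic,
        n_negative=cfg.n_negative,
        true_positive_fraction=cfg.true_positive_fraction,
        neg_mean=cfg.neg_mean,
        pos_fold=cfg.pos_fold,
        cv=cfg.od_cv,
        seed=seed + 2,
    )
    write_plate(plate, out / "plate.tsv")

    series, series_truth = gen_inhibition_series(
        Imax=cfg.imax, IC50=cfg.ic50, hill=cfg.hill, cv=cfg.inhibition_cv, seed=seed + 3
    )
    low_a, _ = gen_inhibition_series(
        Imax=8.5, IC50=cfg.ic50, hill=cfg.hill, cv=cfg.inhibition_cv,
        seed=seed + 4, inhibitor="SP-MDH",
    )
    low_b, _ = gen_inhibition_series(
        Imax=8.3, IC50=cfg.ic50, hill=cfg.hill, cv=cfg.inhibition_cv,
        seed=seed + 5, inhibitor="ES-MDH",
    )
    write_inhibition([series, low_a, low_b], out / "inhibition.tsv")

    table, tpm_truth = gen_tpm(dispersion=cfg.tpm_dispersion, seed=seed + 6)
    write_quant_tree(table, out / "quant")
    table.mapping.to_csv(out / "mapping.tsv", sep="\t", index=False)
    table.samples.to_csv(out / "samples.tsv", sep="\t", index=False)

    truth = {
        "seed": seed,
        "species_tree_topology": "((((CF,PP),SP),(CO,ES)),PC)",
        "outgroup": "PC",
        "plate": plate_truth,
        "inhibition": series_truth,
        "tpm": tpm_truth,
        "epitope_regions": [list(r) for r in cfg.epitope_regions],
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return truth
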