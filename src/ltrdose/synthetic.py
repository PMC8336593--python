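"""Synthetic dose–response benchmarks with known ground truth.

The generator emulates the structure of a combination-screening panel: a set
of drugs screened pairwise over a 4 x 4 concentration grid in each cell line
(plus per-drug monotherapy rows at the same concentration levels), a binary
substructure fingerprint per drug, and per-cell-line omics blocks with
heavy-tailed feature variances.  Responses are %-growth values relative to
an untreated control.

The ground-truth response surface is drawn from the extended LTR model class
itself (identity activation by default), over the encoded feature space of
the panel, which makes prediction-level recovery experiments well-posed: the
target function is inside the model class, so failures point at the
optimizer, not at misspecification.  A configurable share of the signal is
routed through chemistry — substructure-driven drug main effects plus a
low-rank fingerprint–fingerprint interaction — so that drug effects can
transfer to entirely new drug pairs through shared substructure bits.
A separate "misspecified" mode generates
a saturating Hill-type interaction surface outside the model class for
robustness testing.

Noise-free responses are kept on the generated object for evaluation but are
never placed into the public response table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd

from .core import LTRParameters, eval_extended
from .features import MONO, FeatureLayout, Vocabulary, assemble
from .trainer import HyperParams, init_params

__all__ = ["PanelSpec", "GroundTruth", "PanelData", "make_ground_truth",
           "simulate_panel", "simulate_auxiliary"]


@dataclass
class PanelSpec:
    """Study conditions for one synthetic screening panel.

    Defaults describe a small but structurally complete panel: every pair of
    10 drugs screened on a 4 x 4 dose grid in 5 cell lines, responses
    centered at 40 %-growth with a 30-point spread and 5 points of additive
    measurement noise (absolute, on the %-growth scale).
    """

    n_drugs: int = 10
    n_cells: int = 5
    n_conc: int = 4
    pair_fraction: float = 1.0
    # "random": a seeded subset of all pairs; "matching": a disjoint perfect
    # matching (every drug screened in exactly one combination), the sparsest
    # realistic screen — holding out a pair then removes both drugs from all
    # training combinations
    pair_structure: str = "random"
    noise_sd: float = 5.0
    response_offset: float = 40.0
    response_scale: float = 30.0
    seed: int = 0
    # ground-truth model
    truth_rank: int = 10
    truth_degree: int = 5
    truth_activation: str = "identity"
    aux_signal_share: float = 0.0     # share of signal variance routed via aux features
    aux_rank: int = 2                 # rank of the substructure-interaction surface
    # one-hot blocks the index component may use; dropping the drug blocks
    # routes every drug effect through chemistry (fingerprints), emulating a
    # screen whose pair-specific effects are substructure-driven
    index_active_blocks: tuple[str, ...] = (
        "drug_a_onehot", "drug_b_onehot", "conc_a_onehot",
        "conc_b_onehot", "cell_onehot",
    )
    misspecified: bool = False        # Hill-type surface outside the model class
    planted_feature: str | None = None  # omics column name carrying the aux signal
    # auxiliary tables
    n_fp_bits: int = 32
    n_constant_fp_bits: int = 2       # forced all-one / all-zero bits
    omics_features: dict[str, int] = field(default_factory=lambda: {"expression": 60, "cnv": 40})

    def __post_init__(self) -> None:
        if self.n_conc < 2:
            raise ValueError("need at least two concentration levels")
        if not 0.0 < self.pair_fraction <= 1.0:
            raise ValueError("pair_fraction must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.aux_signal_share <= 1.0:
            raise ValueError("aux_signal_share must lie in [0, 1]")

    @property
    def drugs(self) -> list[str]:
        return [f"D{i:03d}" for i in range(self.n_drugs)]

    @property
    def cells(self) -> list[str]:
        return [f"C{i:03d}" for i in range(self.n_cells)]


@dataclass
class ChemInteraction:
    """Substructure-driven drug effects: per-slot main effects plus a
    low-rank interaction,

        g(fp_a, fp_b) = sum_t lam_t (<u_t, fp_a> + <v_t, fp_b>)
                      + w * sum_t lam_t <u_t, fp_a> <v_t, fp_b>.

    The main-effect part emulates structure–potency relationships (a drug's
    effect follows from the substructures it carries) and the product part
    emulates substructure-level interaction between the paired drugs.  When
    the drugs of a held-out pair appear in no training combination, one-hot
    identity features carry no information about either part, while shared
    fingerprint bits transfer both.  Monotherapy rows see only the drug-A
    main effect (fp_b is all zero)."""

    lam: np.ndarray          # (r,)
    U: np.ndarray            # (n_bits, r)
    V: np.ndarray            # (n_bits, r)
    inter_weight: float = 0.5

    def evaluate(self, fp_a: np.ndarray, fp_b: np.ndarray) -> np.ndarray:
        ga = fp_a @ self.U
        gb = fp_b @ self.V
        return (ga + gb) @ self.lam + self.inter_weight * (ga * gb) @ self.lam


@dataclass
class GroundTruth:
    """Hidden generating model: one LTR draw over the index features and an
    optional substructure-interaction component over the fingerprints,
    combined as

        truth = offset + scale * z,   z = normalized( sqrt(1-s)*z_idx + sqrt(s)*z_aux )

    where each component is standardized over the full panel."""

    index_model: LTRParameters | None
    aux_model: ChemInteraction | None
    layout: FeatureLayout
    offset: float
    scale: float
    share: float


@dataclass
class PanelData:
    spec: PanelSpec
    records: pd.DataFrame            # public table (noisy responses)
    truth: np.ndarray                # hidden noise-free responses, same order
    fingerprints: pd.DataFrame
    omics: dict[str, pd.DataFrame]
    vocab: Vocabulary
    ground_truth: GroundTruth | None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent named RNG streams fanned out from one panel seed."""
    root = np.random.SeedSequence(seed)
    names = ["pairs", "fingerprints", "omics", "truth_idx", "truth_aux",
             "noise", "hill"]
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _grid(spec: PanelSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Enumerate measured combination and monotherapy rows (no responses)."""
    if spec.pair_structure == "matching":
        order = rng.permutation(spec.n_drugs)
        drugs = spec.drugs
        pairs = [tuple(sorted((drugs[order[2 * i]], drugs[order[2 * i + 1]])))
                 for i in range(spec.n_drugs // 2)]
        pairs.sort()
    elif spec.pair_structure == "random":
        pairs = list(combinations(spec.drugs, 2))
        if spec.pair_fraction < 1.0:
            k = max(1, int(round(spec.pair_fraction * len(pairs))))
            idx = rng.choice(len(pairs), size=k, replace=False)
            pairs = [pairs[i] for i in sorted(idx)]
    else:
        raise ValueError(f"unknown pair_structure {spec.pair_structure!r}")
    rows = []
    levels = range(1, spec.n_conc + 1)
    for a, b in pairs:
        for cell in spec.cells:
            for ca in levels:
                for cb in levels:
                    rows.append((a, b, ca, cb, cell))
    for d in spec.drugs:
        for cell in spec.cells:
            for ca in levels:
                rows.append((d, MONO, ca, 0, cell))
    rec = pd.DataFrame(rows, columns=["drug_a", "drug_b", "conc_a", "conc_b", "cell_line"])
    rec["response"] = 0.0
    return rec


def _masked_truth_model(spec: PanelSpec, layout: FeatureLayout, rng: np.random.Generator,
                        active_blocks: list[str], degree: int | None = None,
                        rank: int | None = None) -> LTRParameters:
    """Draw an LTR parameter set whose input scaling is zero outside the
    active feature blocks (the constant column is always active)."""
    hyper = HyperParams(
        n_d=degree or spec.truth_degree,
        n_t=max(rank if rank is not None else spec.truth_rank, 1),
        n_k=min(layout.width, 20), activation=spec.truth_activation,
        epochs=1,
    )
    params = init_params(hyper, layout.width, 1, seed=int(rng.integers(2**31)))
    lam_u = np.zeros(layout.width)
    for name in active_blocks + ["constant"]:
        b = layout.block(name)
        lam_u[b.slice] = 1.0
    params.lambda_u = lam_u
    params.lam = rng.standard_normal(params.rank)
    if spec.truth_rank == 0:
        params.lam[:] = 0.0
    return params


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def _hill_surface(spec: PanelSpec, rec: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Bliss-style product of per-drug saturating dose effects plus a random
    pairwise interaction; deliberately outside the LTR model class."""
    levels = np.arange(1, spec.n_conc + 1)
    effect: dict[str, np.ndarray] = {}
    for d in spec.drugs:
        ec50 = rng.uniform(1.0, spec.n_conc)
        h = rng.uniform(0.8, 2.5)
        effect[d] = 1.0 / (1.0 + (ec50 / levels) ** h)
    cell_factor = {c: rng.uniform(0.6, 1.4) for c in spec.cells}
    inter = {}
    out = np.zeros(len(rec))
    for i, row in enumerate(rec.itertuples(index=False)):
        ea = effect[row.drug_a][row.conc_a - 1]
        if row.drug_b == MONO:
            eb, syn = 0.0, 0.0
        else:
            eb = effect[row.drug_b][row.conc_b - 1]
            key = (row.drug_a, row.drug_b)
            if key not in inter:
                inter[key] = rng.normal(0.0, 0.3)
            syn = inter[key] * ea * eb
        growth = (1.0 - ea) * (1.0 - eb) * cell_factor[row.cell_line] - syn
        out[i] = growth
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_auxiliary(spec: PanelSpec) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Generate the fingerprint and omics tables for a panel spec.

    Fingerprints are Bernoulli per bit with bit prevalences spread over
    (0.15, 0.85) so substructures are shared across drugs; the first
    ``n_constant_fp_bits`` bits alternate all-one / all-zero to exercise
    constant-bit filtering downstream.  Omics features are zero-mean normal
    with log-normal per-feature standard deviations (heavy-tailed variance
    spectrum, as real omics panels show).
    """
    streams = _streams(spec.seed)
    rng = streams["fingerprints"]
    bits = np.zeros((spec.n_drugs, spec.n_fp_bits), dtype=int)
    for j in range(spec.n_fp_bits):
        if j < spec.n_constant_fp_bits:
            bits[:, j] = j % 2
        else:
            p = rng.uniform(0.15, 0.85)
            bits[:, j] = rng.random(spec.n_drugs) < p
    fp = pd.DataFrame(bits, index=spec.drugs,
                      columns=[f"bit{j:03d}" for j in range(spec.n_fp_bits)])
    fp.index.name = "drug"

    rng = streams["omics"]
    omics: dict[str, pd.DataFrame] = {}
    for name, p in spec.omics_features.items():
        sds = rng.lognormal(mean=0.0, sigma=1.0, size=p)
        values = rng.standard_normal((spec.n_cells, p)) * sds
        table = pd.DataFrame(values, index=spec.cells,
                             columns=[f"{name}{j:03d}" for j in range(p)])
        table.index.name = "cell_line"
        omics[name] = table
    return fp, omics


def make_ground_truth(spec: PanelSpec, layout: FeatureLayout) -> GroundTruth:
    """Draw the hidden generating model over an encoded panel layout.

    The index component may use every one-hot block; the auxiliary component
    may not see the drug-identity one-hots, so whatever signal it carries
    about the drugs flows through fingerprint bits only and remains
    predictable for held-out drug pairs.
    """
    streams = _streams(spec.seed)
    idx_model = _masked_truth_model(spec, layout, streams["truth_idx"],
                                    list(spec.index_active_blocks))
    aux_model = None
    if spec.aux_signal_share > 0:
        rng = streams["truth_aux"]
        n_bits = layout.block("fp_a").width
        r = max(spec.aux_rank, 1)
        aux_model = ChemInteraction(
            lam=rng.standard_normal(r),
            U=rng.standard_normal((n_bits, r)) / np.sqrt(n_bits),
            V=rng.standard_normal((n_bits, r)) / np.sqrt(n_bits),
        )
    return GroundTruth(
        index_model=idx_model, aux_model=aux_model, layout=layout,
        offset=spec.response_offset, scale=spec.response_scale,
        share=spec.aux_signal_share,
    )


def _truth_values(spec: PanelSpec, truth: GroundTruth, X: np.ndarray,
                  X_planted: np.ndarray | None) -> np.ndarray:
    s = truth.share
    z_idx = _standardize(eval_extended(truth.index_model, X)[:, 0])
    if s > 0:
        if X_planted is not None:
            z_aux = _standardize(X_planted)
        else:
            fa = X[:, truth.layout.block("fp_a").slice]
            fb = X[:, truth.layout.block("fp_b").slice]
            z_aux = _standardize(truth.aux_model.evaluate(fa, fb))
        z = np.sqrt(1.0 - s) * z_idx + np.sqrt(s) * z_aux
    else:
        z = z_idx
    z = _standardize(z)   # exact: panel SD equals the requested scale
    return truth.offset + truth.scale * z


def simulate_panel(spec: PanelSpec) -> PanelData:
    """Generate a full synthetic panel: records, hidden truth, auxiliaries.

    The public response column is ``truth + N(0, noise_sd^2)``; the
    noise-free values are kept on the returned object only.
    """
    streams = _streams(spec.seed)
    rec = _grid(spec, streams["pairs"])
    fp, omics = simulate_auxiliary(spec)
    vocab = Vocabulary(drugs=tuple(spec.drugs),
                       conc_levels=tuple(range(1, spec.n_conc + 1)),
                       cells=tuple(spec.cells))
    X, layout = assemble(rec, vocab, fingerprints=fp, omics=omics)

    if spec.misspecified:
        raw = _hill_surface(spec, rec, streams["hill"])
        truth_values = spec.response_offset + spec.response_scale * _standardize(raw)
        ground_truth = None
    else:
        ground_truth = make_ground_truth(spec, layout)
        planted = None
        if spec.planted_feature is not None:
            col = layout.column_names.index(spec.planted_feature)
            planted = X[:, col]
        truth_values = _truth_values(spec, ground_truth, X, planted)

    noise = streams["noise"].normal(0.0, spec.noise_sd, size=len(rec))
    rec = rec.copy()
    rec["response"] = truth_values + noise
    return PanelData(spec=spec, records=rec, truth=truth_values,
                     fingerprints=fp, omics=omics, vocab=vocab,
                     ground_truth=ground_truth)


def write_panel(panel: PanelData, outdir, include_truth: bool = True) -> dict[str, str]:
    """Write the panel as delimited text; the hidden truth goes to its own
    clearly named file, never into the public response table."""
    import os
    import yaml

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    from .features import write_responses
    paths["responses"] = os.path.join(outdir, "responses.tsv")
    write_responses(panel.records, paths["responses"])
    paths["fingerprints"] = os.path.join(outdir, "fingerprints.tsv")
    panel.fingerprints.to_csv(paths["fingerprints"], sep="\t")
    for name, table in panel.omics.items():
        paths[f"omics_{name}"] = os.path.join(outdir, f"omics_{name}.tsv")
        table.to_csv(paths[f"omics_{name}"], sep="\t")
    if include_truth:
        paths["truth"] = os.path.join(outdir, "truth_hidden.tsv")
        pd.DataFrame({"truth": panel.truth}).to_csv(paths["truth"], sep="\t", index=False)
    spec_dict = asdict(panel.spec)
    paths["spec"] = os.path.join(outdir, "panel_spec.yaml")
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(spec_dict, fh)
    return paths
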