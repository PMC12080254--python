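"""Synthetic rosters, evidence tables and training sets with known ground truth.

Structures are assembled from a motif grammar — enumerable families of valid
SMILES emulating the chemical classes reported from permafrost active-layer
soil: perfluoroalkyl (PFAS-like) chains, organophosphate esters, chlorinated
aromatics, small polar halogenated synthetics, brominated natural products,
terpenoid-like naturals and plain aliphatics.  Building from a grammar (rather
than random SMILES mutation) guarantees every structure parses and gives
controllable fingerprint signatures.

The planted ground truth is a monotone rule on computed descriptors
(positive iff the log P estimate falls below a cutoff AND the molecule is
halogenated), so the rule screen, the ML screen and the explanation ranking
can all be checked against a truth the generator wrote down.  The default
composition targets roughly one third positives out of a 542-compound roster
with origin mix 287/130/125 (synthetic/natural/undefined).

The ML training-set generator lays a deterministic stratified backbone over
the full grammar before random fill, so compounds resampled from the training
distribution always sit inside the training point cloud — by construction the
applicability domain covers them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from .io import CompoundRecord, canonical_smiles

# ---------------------------------------------------------------------------
# motif grammar


def _pfas_family() -> list[str]:
    heads = ["OC(=O)", "OS(=O)(=O)", "OCC", "NC(=O)", "OCCOC(=O)", ""]
    return [h + "C(F)(F)" * n + "F" for h in heads for n in range(2, 14)]


def _organophosphate_family() -> list[str]:
    rs = ["C", "CC", "CCC", "CCCC", "CCCCC", "CC(C)C", "c1ccccc1", "CCCl", "CC(C)OC"]
    out = []
    for r1, r2, r3 in itertools.combinations_with_replacement(rs, 3):
        out.append(f"O=P(O{r1})(O{r2})O{r3}")
    return out


def _halo_ring_family(halogen: str, cores: list[str], slots: int = 5) -> list[str]:
    """Cores are format templates with ``slots`` substitutable ring positions."""
    out = []
    for core in cores:
        for pattern in itertools.product(["c", f"c({halogen})"], repeat=slots):
            if not any(p != "c" for p in pattern):
                continue
            out.append(core.format("".join(pattern)))
    return out


def _chloroaromatic_family() -> list[str]:
    plain = _halo_ring_family(
        "Cl", ["c1{}1", "Oc1{}1", "COc1{}1", "OC(=O)c1{}1"]
    )
    # hydroxylated / carboxylated cores: polar enough to stay water-mobile
    polar = _halo_ring_family(
        "Cl", ["Oc1c(O){}1", "OC(=O)c1c(O){}1", "Oc1c(CO){}1"], slots=4
    )
    return plain + polar


def _bromonatural_family() -> list[str]:
    ring = _halo_ring_family("Br", ["Oc1{}1", "COc1{}1"])
    polar_ring = _halo_ring_family("Br", ["Oc1c(O){}1", "OC(=O)c1c(O){}1"], slots=4)
    # bromopyrrole series (halogenated pyrroles are classic marine naturals)
    pyrroles = _halo_ring_family("Br", ["c1{}[nH]1"], slots=3)
    vinylic = ["BrC=C", "BrCC=C", "BrCCC=C", "BrC=CC", "OCC(Br)CBr", "OCC(Br)CCBr"]
    return ring + polar_ring + pyrroles + vinylic


def _halopolar_family() -> list[str]:
    """Small polar halogenated compounds (halo acids, alcohols, amides,
    nitriles, sulfonates) — the grammar's reservoir of mobile halogenated
    structures."""
    heads = ["OC(=O)", "OCC(O)", "NC(=O)", "OS(=O)(=O)", "N#C", "OCC(=O)", "OC(=O)C(O)"]
    out = []
    for x in ("F", "Cl", "Br"):
        tails = [f"C{x}", f"C({x}){x}", f"C({x})({x}){x}",
                 f"CC{x}", f"C({x})C{x}", f"CC({x}){x}", f"C({x})CC{x}"]
        for h in heads:
            out += [h + t for t in tails]
        out += [f"OCC{x}", f"OCC({x}){x}", f"NCC{x}", f"OCC(O)C{x}",
                f"OCC(O)C({x}){x}"]
        # halomethane, haloether and secondary-haloamide series
        out += [f"{x}C{x}", f"{x}C({x}){x}", f"{x}C({x})({x}){x}",
                f"{x}CCOCC{x}", f"{x}CCOC", f"{x}CC(=O)NC", f"{x}CC(=O)NCC{x}"]
    return out


def _fluoropolar_family() -> list[str]:
    """Short-chain polyfluorinated compounds with polar heads (the mobile
    end of the PFAS spectrum)."""
    heads = ["OC(=O)", "OS(=O)(=O)", "OCC(O)", "NC(=O)", "OC(=O)C(O)", "NS(=O)(=O)"]
    return [h + "C(F)(F)" * n + "F" for h in heads for n in range(1, 4)]


def _terpenoid_family() -> list[str]:
    """Terpenoid-like naturals, built as contiguous scaffold series
    (monocyclic menthane-like, cyclic ketones, acyclic prenol chains)."""
    limonene = ["CC1=CCC(CC1)C(C)" + "C" * n for n in range(0, 4)]
    menthol = ["CC(C)C1CCC(C" + "C" * n + ")CC1O" for n in range(0, 4)]
    carvone = ["CC1=CCC(CC1=O)C(C)" + "C" * n for n in range(0, 4)]
    prenols = ["CC(C)=CCC" + "C" * n + "O" for n in range(1, 9)]
    geraniol = ["CC(C)=CCCC(C)=CC" + "C" * n + "O" for n in range(0, 4)]
    return limonene + menthol + carvone + prenols + geraniol


def _aliphatic_family() -> list[str]:
    alkanes = ["C" * n for n in range(5, 17)]
    alcohols = ["OC" + "C" * n for n in range(3, 13)]
    acids = ["OC(=O)" + "C" * n for n in range(2, 13)]
    branched = ["CC(C)" + "C" * n for n in range(3, 10)]
    diacids = ["OC(=O)" + "C" * n + "C(=O)O" for n in range(2, 8)]
    esters = ["CCOC(=O)" + "C" * n for n in range(2, 8)]
    return alkanes + alcohols + acids + branched + diacids + esters


#: family -> (SMILES builder, origins that may plausibly carry the motif)
_FAMILIES: dict[str, tuple] = {
    "pfas": (_pfas_family, ("synthetic",)),
    "organophosphate": (_organophosphate_family, ("synthetic",)),
    "chloroaromatic": (_chloroaromatic_family, ("synthetic", "natural", "undefined")),
    "halopolar": (_halopolar_family, ("synthetic", "natural", "undefined")),
    "fluoropolar": (_fluoropolar_family, ("synthetic", "undefined")),
    "bromonatural": (_bromonatural_family, ("natural", "undefined")),
    "terpenoid": (_terpenoid_family, ("natural",)),
    "aliphatic": (_aliphatic_family, ("natural", "undefined")),
}


def enumerate_motif_space() -> pd.DataFrame:
    """All grammar variants: canonical SMILES, family, eligible origins.

    Deterministic order; structural duplicates (e.g. symmetric ring
    substitution patterns) are merged at build time.
    """
    rows = []
    seen: set[str] = set()
    for family, (builder, origins) in _FAMILIES.items():
        for smi in builder():
            can = canonical_smiles(smi)
            if can is None:
                raise RuntimeError(f"grammar produced invalid SMILES {smi!r}")
            if can in seen:
                continue
            seen.add(can)
            rows.append({"smiles": can, "family": family, "origins": origins})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generator spec


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic data set.

    Defaults emulate the screened permafrost roster: 542 compounds with
    origin mix 0.530/0.240/0.230 (giving 287/130/125 by largest remainder),
    experimental-property coverage for about a quarter of the roster, a known
    reference list carrying 7 PMT + 4 vPvM + 4 PMT&vPvM entries, and
    non-extractable-residue concentrations three orders of magnitude above
    the extractable fraction.
    """

    seed: int
    n_total: int = 542
    origin_fractions: dict = field(
        default_factory=lambda: {"synthetic": 0.530, "natural": 0.240, "undefined": 0.230}
    )
    #: structural motif mix per origin stratum
    family_weights: dict = field(
        default_factory=lambda: {
            "synthetic": {"pfas": 0.22, "organophosphate": 0.30,
                          "chloroaromatic": 0.18, "halopolar": 0.28,
                          "fluoropolar": 0.02},
            "natural": {"terpenoid": 0.13, "aliphatic": 0.20,
                        "bromonatural": 0.33, "chloroaromatic": 0.10,
                        "halopolar": 0.24},
            "undefined": {"halopolar": 0.34, "chloroaromatic": 0.28,
                          "bromonatural": 0.18, "aliphatic": 0.20},
        }
    )
    property_coverage: float = 0.25
    label_noise: float = 0.0
    known_positive_counts: dict = field(
        default_factory=lambda: {"PMT": 7, "vPvM": 4, "PMT_and_vPvM": 4}
    )
    known_negative_count: int = 20
    # planted decision rule on named descriptors
    logp_feature: str = "logP_estimate"
    logp_cutoff: float = 2.0
    halogen_feature: str = "halogen_count"
    # ML training set
    n_train: int = 400
    # concentrations
    n_sites: int = 8
    lat_range: tuple[float, float] = (31.5, 38.5)
    obs_rate: float = 0.6           # fraction of compounds with observations
    ner_rate: float = 0.3           # share of observations from the NER fraction
    ef_log_mean: float = math.log(40.0)
    ef_log_sd: float = 1.2
    ner_ef_ratio: float = 1000.0    # location shift of NER over EF
    lat_trend: float = 0.08         # per-degree southward concentration increase

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if abs(sum(self.origin_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("origin fractions must sum to 1")
        for rate in (self.property_coverage, self.label_noise, self.obs_rate,
                     self.ner_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


def origin_counts(spec: GeneratorSpec) -> dict[str, int]:
    """Integer origin counts by largest-remainder apportionment."""
    exact = {o: spec.n_total * f for o, f in spec.origin_fractions.items()}
    counts = {o: int(math.floor(v)) for o, v in exact.items()}
    short = spec.n_total - sum(counts.values())
    for o in sorted(exact, key=lambda o: exact[o] - counts[o], reverse=True)[:short]:
        counts[o] += 1
    return counts


def _planted_rule(spec: GeneratorSpec, desc: pd.DataFrame) -> pd.Series:
    for name in (spec.logp_feature, spec.halogen_feature):
        if name not in desc.columns:
            raise ValueError(f"planted rule references absent feature {name!r}")
    return (desc[spec.logp_feature] < spec.logp_cutoff) & (
        desc[spec.halogen_feature] >= 1
    )


# ---------------------------------------------------------------------------
# roster + truth


def generate_roster(spec: GeneratorSpec) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Sample a roster from the motif grammar plus its ground-truth table.

    Origin labels follow motif-family plausibility; each structure is used at
    most once so the roster is duplicate-free.  The truth table records, per
    compound, the planted positive flag (log P rule) and — for positives — a
    designated hazard class drawn in the proportions of the known reference
    classes.
    """
    rng = np.random.default_rng(spec.seed)
    space = enumerate_motif_space()
    counts = origin_counts(spec)
    if spec.n_total > len(space):
        raise ValueError(
            f"n_total={spec.n_total} exceeds grammar size {len(space)}"
        )

    # shuffled per-family stacks of still-unused variant indices
    by_family: dict[str, list[int]] = {}
    for fam in space["family"].unique():
        idxs = space.index[space["family"] == fam].to_numpy()
        by_family[fam] = list(rng.permutation(idxs))

    chosen: list[tuple[int, str]] = []  # (space index, origin)
    for origin in ("natural", "synthetic", "undefined"):
        need = counts.get(origin, 0)
        if need == 0:
            continue
        weights = spec.family_weights.get(origin)
        if not weights:
            raise ValueError(f"no family weights for origin {origin!r}")
        for fam in weights:
            if origin not in _FAMILIES[fam][1]:
                raise ValueError(f"family {fam!r} not eligible for origin {origin!r}")
        # largest-remainder apportionment of the origin's count over families
        total_w = sum(weights.values())
        exact = {f: need * w / total_w for f, w in weights.items()}
        fam_counts = {f: int(math.floor(v)) for f, v in exact.items()}
        short = need - sum(fam_counts.values())
        for f in sorted(exact, key=lambda f: exact[f] - fam_counts[f],
                        reverse=True)[:short]:
            fam_counts[f] += 1
        # draw; exhausted families spill over to other weighted families
        deficit = 0
        for fam, want in fam_counts.items():
            take = min(want, len(by_family[fam]))
            for _ in range(take):
                chosen.append((int(by_family[fam].pop()), origin))
            deficit += want - take
        while deficit:
            open_fams = [f for f in weights if by_family[f]]
            if not open_fams:
                raise ValueError(
                    f"grammar cannot supply {counts[origin]} {origin} compounds"
                )
            fam = open_fams[int(rng.integers(len(open_fams)))]
            chosen.append((int(by_family[fam].pop()), origin))
            deficit -= 1

    order = rng.permutation(len(chosen))
    records = []
    rows = []
    for rank, j in enumerate(order):
        idx, origin = chosen[j]
        cid = f"SYN{rank:04d}"
        smi = space.iloc[idx]["smiles"]
        records.append(
            CompoundRecord(
                compound_id=cid, name=f"synthetic compound {rank}",
                smiles=smi, origin=origin,
            )
        )
        rows.append({"compound_id": cid, "smiles": smi, "origin": origin,
                     "family": space.iloc[idx]["family"]})
    truth = pd.DataFrame(rows).set_index("compound_id")

    desc = ft.descriptor_matrix(records)[[spec.logp_feature, spec.halogen_feature]]
    truth["true_positive"] = _planted_rule(spec, desc).loc[truth.index]

    classes = list(spec.known_positive_counts)
    weights = np.array([spec.known_positive_counts[c] for c in classes], dtype=float)
    weights /= weights.sum()
    truth["true_class"] = [
        rng.choice(classes, p=weights) if pos else "not_PMT_vPvM"
        for pos in truth["true_positive"]
    ]
    return records, truth


# ---------------------------------------------------------------------------
# property evidence


def generate_properties(
    roster: list[CompoundRecord], truth: pd.DataFrame, spec: GeneratorSpec
) -> pd.DataFrame:
    """Long-format experimental evidence for a coverage sample of the roster.

    Values are drawn inside the half-life / log Koc bands implied by each
    compound's true class, so at zero label noise the rule screen recovers the
    truth exactly for every covered compound; with noise, a covered compound's
    evidence is drawn from the wrong class's bands at the noise rate.
    """
    rng = np.random.default_rng(spec.seed + 1)
    ids = [r.compound_id for r in roster]
    n_cov = int(round(spec.property_coverage * len(ids)))
    covered = rng.choice(ids, size=n_cov, replace=False) if n_cov else []

    rows: list[dict] = []
    flags = ["CMR", "aquatic_tox", "STOT_RE", "endocrine_disruption"]
    for cid in covered:
        cls = truth.loc[cid, "true_class"]
        if spec.label_noise and rng.random() < spec.label_noise:
            cls = "not_PMT_vPvM" if cls != "not_PMT_vPvM" else "PMT"
        if cls == "PMT":
            hl_band, koc_band, tox = (45.0, 58.0), (2.05, 2.90), True
        elif cls in ("vPvM", "PMT_and_vPvM"):
            hl_band, koc_band, tox = (65.0, 300.0), (0.3, 1.90), cls == "PMT_and_vPvM"
        else:
            hl_band, koc_band, tox = (2.0, 38.0), (3.05, 5.50), False

        for _ in range(int(rng.integers(1, 4))):
            rows.append({"compound_id": cid, "property": "half_life_freshwater_d",
                         "value": round(float(rng.uniform(*hl_band)), 2), "ph": ""})
        for _ in range(int(rng.integers(1, 4))):
            rows.append({"compound_id": cid, "property": "log_koc",
                         "value": round(float(rng.uniform(*koc_band)), 3),
                         "ph": round(float(rng.uniform(4.0, 9.0)), 1)})
        if tox:
            rows.append({"compound_id": cid, "property": "tox_flag",
                         "value": str(rng.choice(flags)), "ph": ""})
    return pd.DataFrame(rows, columns=["compound_id", "property", "value", "ph"])


def generate_known_list(truth: pd.DataFrame, spec: GeneratorSpec) -> pd.DataFrame:
    """Known reference list keyed by canonical structure.

    Draws the configured number of entries per listed positive class from the
    truth table (7/4/4 by default) plus a set of evaluated negatives.
    """
    rng = np.random.default_rng(spec.seed + 2)
    rows = []
    for cls, want in spec.known_positive_counts.items():
        pool = truth.index[truth["true_class"] == cls].to_numpy()
        take = rng.choice(pool, size=min(want, len(pool)), replace=False)
        rows += [{"match_key": truth.loc[cid, "smiles"], "listed_class": cls}
                 for cid in take]
    neg_pool = truth.index[~truth["true_positive"]].to_numpy()
    n_neg = min(spec.known_negative_count, len(neg_pool))
    if n_neg:
        take = rng.choice(neg_pool, size=n_neg, replace=False)
        rows += [{"match_key": truth.loc[cid, "smiles"],
                  "listed_class": "not_PMT_vPvM"} for cid in take]
    return pd.DataFrame(rows, columns=["match_key", "listed_class"])


# ---------------------------------------------------------------------------
# ML training data


def generate_training_set(
    spec: GeneratorSpec,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Labeled descriptor matrix standing in for the classifier's training data.

    A deterministic stratified backbone covers the whole motif grammar (every
    ceil(V/n)-th variant in grammar order), the rest is random fill — so the
    training set spans the generator's structure space and compounds drawn
    from the same grammar lie within the applicability domain.  Labels come
    from the planted monotone rule with optional Bernoulli label noise.
    """
    rng = np.random.default_rng(spec.seed + 3)
    space = enumerate_motif_space()
    n = spec.n_train
    V = len(space)
    if n >= V:
        picks = list(range(V)) + list(rng.integers(0, V, size=n - V))
    else:
        stride = math.ceil(V / n)
        backbone = list(range(0, V, stride))
        fill = rng.choice(V, size=n - len(backbone), replace=False)
        picks = backbone + list(fill)

    records = [
        CompoundRecord(compound_id=f"TRN{i:04d}", name=f"training compound {i}",
                       smiles=space.iloc[idx]["smiles"])
        for i, idx in enumerate(picks)
    ]
    feats = ft.descriptor_matrix(records)
    labels = _planted_rule(spec, feats).astype(int)
    if spec.label_noise:
        flip = rng.random(len(labels)) < spec.label_noise
        labels = labels ^ flip.astype(int)
    if labels.nunique() < 2:
        raise ValueError("planted rule produced a single-class training set")
    meta = pd.DataFrame(
        {"compound_id": [r.compound_id for r in records],
         "smiles": [r.smiles for r in records],
         "family": [space.iloc[idx]["family"] for idx in picks],
         "label": labels.to_numpy()}
    ).set_index("compound_id")
    return feats, labels.rename("label"), meta


# ---------------------------------------------------------------------------
# concentrations


def generate_concentrations(
    roster: list[CompoundRecord], spec: GeneratorSpec
) -> pd.DataFrame:
    """Site/depth concentration observations with an EF ≪ NER contrast.

    Extractable-fraction values are log-normal; non-extractable-residue
    values share the shape but sit three orders of magnitude higher by
    default.  A mild per-degree southward multiplier makes site totals rise
    from north to south.
    """
    rng = np.random.default_rng(spec.seed + 4)
    if spec.n_sites == 0:
        return pd.DataFrame(
            columns=["compound_id", "site_id", "latitude", "depth_cm",
                     "fraction", "conc_ng_g_dw"]
        )
    lats = np.linspace(spec.lat_range[1], spec.lat_range[0], spec.n_sites)
    lat_max = spec.lat_range[1]
    rows = []
    for rec in roster:
        if rng.random() > spec.obs_rate:
            continue
        for site in rng.choice(spec.n_sites, size=int(rng.integers(1, 4)),
                               replace=False):
            lat = float(lats[site])
            trend = math.exp(spec.lat_trend * (lat_max - lat))
            is_ner = rng.random() < spec.ner_rate
            loc = spec.ef_log_mean + (math.log(spec.ner_ef_ratio) if is_ner else 0.0)
            value = float(np.exp(rng.normal(loc, spec.ef_log_sd))) * trend
            rows.append({
                "compound_id": rec.compound_id,
                "site_id": f"S{site:02d}",
                "latitude": round(lat, 3),
                "depth_cm": round(float(rng.uniform(0.0, 150.0)), 1),
                "fraction": "NER" if is_ner else "EF",
                "conc_ng_g_dw": round(value, 4),
            })
    return pd.DataFrame(rows, columns=["compound_id", "site_id", "latitude",
                                       "depth_cm", "fraction", "conc_ng_g_dw"])


# ---------------------------------------------------------------------------
# file emission (formats compound_io reads back)


def write_dataset(spec: GeneratorSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a full data set and write every table to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roster, truth = generate_roster(spec)
    paths = {
        "roster": out / "roster.csv",
        "truth": out / "truth.csv",
        "properties": out / "properties.csv",
        "known": out / "known_list.csv",
        "concentrations": out / "concentrations.csv",
        "train_features": out / "train_features.csv",
        "train_meta": out / "train_meta.csv",
    }
    pd.DataFrame(
        [{"compound_id": r.compound_id, "name": r.name, "smiles": r.smiles,
          "origin": r.origin, "cas": ""} for r in roster]
    ).to_csv(paths["roster"], index=False)
    truth.to_csv(paths["truth"])
    generate_properties(roster, truth, spec).to_csv(paths["properties"], index=False)
    generate_known_list(truth, spec).to_csv(paths["known"], index=False)
    generate_concentrations(roster, spec).to_csv(paths["concentrations"], index=False)
    feats, labels, meta = generate_training_set(spec)
    feats.to_csv(paths["train_features"])
    meta.to_csv(paths["train_meta"])
    return paths
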