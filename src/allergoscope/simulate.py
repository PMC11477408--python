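"""Synthetic inputs with the statistical structure the analysis assumes.

Real inputs to this pipeline are assembled fish muscle transcriptomes
with TPM quantification, an allergen protein reference, a parvalbumin
family alignment, and a clinical sIgE/oral-food-challenge cohort.  The
generators here emulate each of these at desk scale with full truth
tables, so every stage can be validated end to end:

* a reference database of allergen families (founder proteins plus
  members mutated at 5-15% of positions);
* per-fish transcript sets planting homologs of database allergens at
  controlled identities and TPM fractions among unrelated decoys, with
  parvalbumin-high and parvalbumin-low abundance regimes and replicate
  samples jittered by log-normal noise;
* a cohort of log-normal sIgE titres with block (within-group vs
  between-group) correlation and challenge outcomes drawn from a
  logistic model on the latent log titre.

Everything is driven by an explicit integer seed through numpy's
Generator; the same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io import AllergenRecord, CohortTable, SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# codons per residue under the standard genetic code
_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()

# the twelve allergen families the analysis is built around: parvalbumin
# plus the glycolytic / structural minor allergens recurrently reported
# in fish, with protein lengths near their real sizes
DEFAULT_FAMILIES = [
    "PV", "GAPDH", "aldolase", "enolase", "creatine_kinase", "tropomyosin",
    "LDH", "TPI", "PK", "PG", "GPI", "alpha_actinin",
]

DEFAULT_FAMILY_LENGTHS = {
    "PV": 110, "GAPDH": 330, "aldolase": 360, "enolase": 430,
    "creatine_kinase": 380, "tropomyosin": 280, "LDH": 330, "TPI": 250,
    "PK": 450, "PG": 450, "GPI": 450, "alpha_actinin": 450,
}

# the five highly expressed non-PV allergens vs the six low-expressed
# minor allergens (each holding a few percent of allergen TPM at most)
MAJOR_FAMILIES = ["GAPDH", "aldolase", "enolase", "creatine_kinase", "tropomyosin"]
MINOR_FAMILIES = ["LDH", "TPI", "PK", "PG", "GPI", "alpha_actinin"]

_ORGANISMS = [
    "Cyprinus carpio", "Gadus morhua", "Salmo salar", "Thunnus albacares",
    "Oreochromis niloticus", "Ctenopharyngodon idella",
]

PV_LOW_FISH = ["tuna", "salmon", "halibut"]
PV_HIGH_FISH = ["cod", "grouper", "grass_carp", "tilapia", "catfish"]


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_to_identity(protein: str, target_identity: float, seed: int | np.random.Generator) -> str:
    """Substitute exactly round(L*(1-identity)) positions of ``protein``.

    Substituted residues always differ from the original, positions are
    distinct, and length is preserved, so the global identity to the
    parent is the target by construction.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target identity must be in (0, 1]")
    if target_identity < 0.2:
        raise ValueError("identities below 0.2 are not reliably recoverable by alignment")
    if len(protein) < 20:
        raise ValueError("protein too short to mutate meaningfully (need length >= 20)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = round(len(protein) * (1.0 - target_identity))
    positions = rng.choice(len(protein), size=n_sub, replace=False)
    seq = list(protein)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != seq[pos]]
        seq[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def reverse_translate(protein: str, seed: int | np.random.Generator) -> str:
    """Random synonymous CDS for a protein (standard genetic code).

    Translating the result in frame +1 recovers the protein exactly.
    Stop codons ('*') are rejected.
    """
    if "*" in protein:
        raise ValueError("protein contains a stop ('*'); cannot reverse-translate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = []
    for aa in protein:
        if aa not in _CODONS:
            raise ValueError(f"no codon for residue {aa!r}")
        options = _CODONS[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def generate_reference_db(
    n_families: int = 12,
    members_per_family: int = 2,
    length: int | dict[str, int] | None = None,
    seed: int = 0,
    family_names: list[str] | None = None,
) -> tuple[list[AllergenRecord], pd.DataFrame]:
    """Allergen reference: independent founders, members mutated 5-15%.

    ``length`` is either one protein length for every family, a
    family -> length map, or None for the built-in near-real sizes
    (parvalbumin 110 aa, the enzyme families 250-450 aa; unknown
    families default to 300).  Returns the records plus a metadata
    frame (id, allergen_name, organism, founder identity).  Family
    founders being independent random proteins keeps cross-family
    identity far below the scan threshold while within-family identity
    stays >= 85%.
    """
    if n_families < 2:
        raise ValueError("need at least 2 families")
    rng = np.random.default_rng(seed)
    names = list(family_names or DEFAULT_FAMILIES)
    while len(names) < n_families:
        names.append(f"FAM{len(names) + 1}")
    names = names[:n_families]
    if length is None:
        lengths = {f: DEFAULT_FAMILY_LENGTHS.get(f, 300) for f in names}
    elif isinstance(length, dict):
        lengths = {f: length.get(f, 300) for f in names}
    else:
        lengths = {f: int(length) for f in names}
    records: list[AllergenRecord] = []
    meta_rows = []
    for fam_idx, family in enumerate(names):
        founder = random_protein(lengths[family], rng)
        for member in range(members_per_family):
            if member == 0:
                seq, identity = founder, 1.0
            else:
                identity = float(rng.uniform(0.85, 0.95))
                seq = mutate_to_identity(founder, identity, rng)
            organism = _ORGANISMS[(fam_idx + member) % len(_ORGANISMS)]
            rec_id = f"{family}_m{member + 1}"
            records.append(AllergenRecord(id=rec_id, name=family, organism=organism, seq=seq))
            meta_rows.append(
                {"id": rec_id, "allergen_name": family, "organism": organism,
                 "founder_identity": round(identity, 4)}
            )
    return records, pd.DataFrame(meta_rows)


@dataclass(frozen=True)
class FishSpec:
    """Generator recipe for one fish's transcript set.

    ``families`` maps allergen family -> target identity of the planted
    homolog; ``pv_fraction`` is the parvalbumin share of total allergen
    TPM (>= 0.5 in the PV-high regime, <= 0.2 in PV-low);
    ``pv_top_share`` is the dominant PV isoform's share of PV TPM.
    """

    name: str
    group: str  # "PV-high" | "PV-low"
    families: dict[str, float]
    pv_fraction: float
    pv_top_share: float = 0.7
    n_pv_isoforms: int = 3
    n_decoys: int = 20
    n_replicates: int = 2
    family_fractions: dict[str, float] | None = None  # overrides uniform split

    def __post_init__(self) -> None:
        if not 0 < self.pv_fraction < 1:
            raise ValueError("pv_fraction must be in (0, 1)")
        if not 0.5 <= self.pv_top_share <= 0.9:
            raise ValueError("pv_top_share outside the dominant-isoform regime [0.5, 0.9]")
        if self.family_fractions is not None:
            if set(self.family_fractions) != set(self.families):
                raise ValueError("family_fractions must cover exactly the spec'd families")
            total = sum(self.family_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"family_fractions sum to {total}, expected 1")
            if "PV" in self.family_fractions and abs(
                self.family_fractions["PV"] - self.pv_fraction
            ) > 1e-9:
                raise ValueError("family_fractions['PV'] must equal pv_fraction")


def default_fish_specs(families: list[str] | None = None) -> list[FishSpec]:
    """Eight fish mirroring the study layout: three parvalbumin-low
    (tuna, salmon, halibut) and five parvalbumin-high (cod, grouper,
    grass carp, tilapia, catfish), two replicate samples each.

    Family TPM fractions follow the observed expression hierarchy: in
    PV-high fish parvalbumin holds 60% of allergen TPM, the five other
    major allergens 6% each and the six minor allergens ~1.7% each; in
    PV-low fish parvalbumin drops to 6%, the majors rise to 14% each
    and the minors to 4% each.  Either way the six top-expressed
    allergens exceed 70% of total allergen expression and every minor
    allergen clears the 1% filter support level.
    """
    families = list(families or DEFAULT_FAMILIES)
    identity_cycle = [0.95, 0.88, 0.80, 0.72, 0.65]
    pv_cycle = [0.90, 0.93, 0.96]  # fish parvalbumins are well conserved
    specs = []
    for f_idx, fish in enumerate(PV_LOW_FISH + PV_HIGH_FISH):
        fam_ids = {
            fam: (pv_cycle[f_idx % len(pv_cycle)] if fam == "PV"
                  else identity_cycle[(f_idx + i) % len(identity_cycle)])
            for i, fam in enumerate(families)
        }
        majors = [f for f in families if f in MAJOR_FAMILIES]
        minors = [f for f in families if f not in MAJOR_FAMILIES and f != "PV"]
        if fish in PV_LOW_FISH:
            pv_frac, major_total = 0.06, 0.70
        else:
            pv_frac, major_total = 0.60, 0.30
        minor_total = 1.0 - pv_frac - major_total
        fractions = {"PV": pv_frac}
        fractions.update({f: major_total / len(majors) for f in majors})
        fractions.update({f: minor_total / len(minors) for f in minors})
        specs.append(
            FishSpec(
                name=fish,
                group="PV-low" if fish in PV_LOW_FISH else "PV-high",
                families=fam_ids,
                pv_fraction=pv_frac,
                pv_top_share=0.7,
                n_pv_isoforms=2 if fish in PV_LOW_FISH else 3,
                family_fractions=fractions,
            )
        )
    return specs


@dataclass
class TranscriptomeSet:
    """Generated transcripts + TPM table + complete truth table."""

    transcripts: list[SequenceRecord]
    tpm: pd.DataFrame
    truth: pd.DataFrame
    fish_groups: dict[str, str]
    seed: int


def generate_transcriptome_set(
    db: list[AllergenRecord],
    fish_specs: list[FishSpec] | None = None,
    seed: int = 0,
    total_tpm: float = 1e6,
    allergen_fraction: float = 0.3,
    noise_sigma: float = 0.1,
    utr_range: tuple[int, int] = (30, 90),
) -> TranscriptomeSet:
    """Plant allergen homologs among decoys and quantify them as TPMs.

    Per fish, each requested family contributes one planted homolog
    (parvalbumin contributes ``n_pv_isoforms``) built by mutating a
    database member to the target identity, reverse-translating, and
    flanking with random UTRs.  Decoys are random coding sequences.
    Allergen families split ``allergen_fraction`` of the TPM budget
    according to the parvalbumin regime; decoys take the rest.
    Replicate samples are jittered by log-normal noise (sigma on the
    natural-log scale) and renormalised so every sample sums to
    ``total_tpm``.
    """
    if not 0 < allergen_fraction < 1:
        raise ValueError("allergen_fraction must be in (0, 1)")
    fish_specs = fish_specs or default_fish_specs()
    rng = np.random.default_rng(seed)
    by_family: dict[str, list[AllergenRecord]] = {}
    for rec in db:
        by_family.setdefault(rec.name, []).append(rec)

    transcripts: list[SequenceRecord] = []
    truth_rows = []
    tpm_cols: dict[str, pd.Series] = {}

    for spec in fish_specs:
        unknown = set(spec.families) - set(by_family)
        if unknown:
            raise ValueError(f"{spec.name}: families not in database: {sorted(unknown)}")
        fish_ids: list[str] = []
        base_tpm: list[float] = []

        others = [f for f in spec.families if f != "PV"]
        other_fraction = (1.0 - spec.pv_fraction) / len(others) if others else 0.0
        counter = 0
        for family, identity in spec.families.items():
            if spec.family_fractions is not None:
                fam_fraction = spec.family_fractions[family]
            elif family == "PV":
                fam_fraction = spec.pv_fraction
            else:
                fam_fraction = other_fraction
            if family == "PV":
                n_iso = spec.n_pv_isoforms
                # dominant top isoform, remainder split evenly
                if n_iso == 1:
                    iso_shares = [1.0]
                else:
                    rest = (1.0 - spec.pv_top_share) / (n_iso - 1)
                    iso_shares = [spec.pv_top_share] + [rest] * (n_iso - 1)
            else:
                n_iso = 1
                iso_shares = [1.0]
            members = by_family[family]
            for iso, share in enumerate(iso_shares):
                source = members[rng.integers(len(members))]
                protein = mutate_to_identity(source.seq, identity, rng)
                cds = reverse_translate(protein, rng)
                utr5 = "".join(rng.choice(list("ACGT"), size=rng.integers(*utr_range)))
                utr3 = "".join(rng.choice(list("ACGT"), size=rng.integers(*utr_range)))
                counter += 1
                tid = f"{spec.name}_t{counter:03d}"
                transcripts.append(SequenceRecord(id=tid, description=tid, seq=utr5 + cds + utr3))
                fish_ids.append(tid)
                base_tpm.append(total_tpm * allergen_fraction * fam_fraction * share)
                truth_rows.append(
                    {"transcript_id": tid, "fish": spec.name, "source_allergen": source.id,
                     "family": family, "target_identity": identity, "isoform": iso + 1,
                     "base_tpm": base_tpm[-1], "is_decoy": False, "protein": protein}
                )
        decoy_budget = total_tpm * (1.0 - allergen_fraction)
        decoy_weights = rng.dirichlet(np.ones(spec.n_decoys)) if spec.n_decoys else []
        for d in range(spec.n_decoys):
            protein = random_protein(int(rng.integers(80, 160)), rng)
            cds = reverse_translate(protein, rng)
            utr5 = "".join(rng.choice(list("ACGT"), size=rng.integers(*utr_range)))
            utr3 = "".join(rng.choice(list("ACGT"), size=rng.integers(*utr_range)))
            counter += 1
            tid = f"{spec.name}_t{counter:03d}"
            transcripts.append(SequenceRecord(id=tid, description=tid, seq=utr5 + cds + utr3))
            fish_ids.append(tid)
            base_tpm.append(decoy_budget * float(decoy_weights[d]))
            truth_rows.append(
                {"transcript_id": tid, "fish": spec.name, "source_allergen": "",
                 "family": "", "target_identity": np.nan, "isoform": 0,
                 "base_tpm": base_tpm[-1], "is_decoy": True, "protein": ""}
            )
        base = np.array(base_tpm)
        for rep in range(1, spec.n_replicates + 1):
            jitter = np.exp(rng.normal(0.0, noise_sigma, size=len(base)))
            values = base * jitter
            values *= total_tpm / values.sum()
            tpm_cols[f"{spec.name}_{rep}"] = pd.Series(values, index=fish_ids)

    tpm = pd.DataFrame(tpm_cols).fillna(0.0)
    tpm = tpm.loc[[t.id for t in transcripts]]
    return TranscriptomeSet(
        transcripts=transcripts,
        tpm=tpm,
        truth=pd.DataFrame(truth_rows),
        fish_groups={s.name: s.group for s in fish_specs},
        seed=seed,
    )


DEFAULT_ANALYTE_GROUPS = {
    **{f: "PV-low" for f in PV_LOW_FISH},
    **{f: "PV-high" for f in PV_HIGH_FISH},
    "herring": "PV-high",
    "rGad_c_1": "PV-high",
    "rCyp_c_1": "PV-high",
}


@dataclass
class CohortTruth:
    """Generating parameters of a synthetic cohort."""

    analyte_groups: dict[str, str]
    mu: dict[str, float]
    sigma: float
    rho_within: float
    rho_between: float
    alpha: dict[str, float]
    beta: float
    latent: pd.DataFrame = field(repr=False, default=None)
    seed: int = 0


def generate_cohort(
    n_subjects: int = 188,
    analyte_groups: dict[str, str] | None = None,
    rho_within: float = 0.8,
    rho_between: float = 0.2,
    mu: dict[str, float] | None = None,
    sigma: float = 0.8,
    alpha: dict[str, float] | None = None,
    beta: float = 1.5,
    ofc_counts: dict[str, int] | None = None,
    seed: int = 0,
    clip: tuple[float, float] = (0.01, 100.0),
) -> tuple[CohortTable, CohortTruth]:
    """Simulate an sIgE cohort with block correlation and OFC outcomes.

    Latent log10 titres are multivariate normal with correlation
    ``rho_within`` inside an analyte group and ``rho_between`` across
    groups; measured sIgE is 10**latent clipped to the assay's
    reportable range.  For each challenged fish, allergy is Bernoulli
    with logit ``alpha[fish] + beta * z`` where z is the subject's
    standardised latent titre for that fish's analyte; OFC labels are
    assigned to the first ``ofc_counts[fish]`` subjects (deterministic
    subset), everyone else stays untested.
    """
    groups = analyte_groups or dict(DEFAULT_ANALYTE_GROUPS)
    analytes = list(groups)
    k = len(analytes)
    group_vec = np.array([groups[a] for a in analytes])
    corr = np.where(group_vec[:, None] == group_vec[None, :], rho_within, rho_between)
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"block structure (rho_within={rho_within}, rho_between={rho_between}) "
            "is not positive definite"
        ) from None
    mu = mu or {a: (0.3 if groups[a] == "PV-high" else -0.3) for a in analytes}
    alpha = alpha or {"grass_carp": 1.2, "salmon": -1.2}
    ofc_counts = ofc_counts or {"grass_carp": 74, "salmon": 72}

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_subjects, k)) @ chol.T
    latent = z * sigma + np.array([mu[a] for a in analytes])
    sige = np.clip(10.0 ** latent, *clip)
    subjects = [f"S{i + 1:03d}" for i in range(n_subjects)]
    sige_df = pd.DataFrame(sige, index=subjects, columns=analytes)
    latent_df = pd.DataFrame(latent, index=subjects, columns=analytes)

    ofc = pd.DataFrame("untested", index=subjects, columns=sorted(alpha))
    for fish in sorted(alpha):
        if fish not in groups:
            raise ValueError(f"OFC fish {fish!r} has no analyte")
        n_ofc = min(ofc_counts.get(fish, 0), n_subjects)
        zi = (latent_df[fish] - mu[fish]) / sigma
        logits = alpha[fish] + beta * zi.to_numpy()
        allergic = rng.random(n_subjects) < 1.0 / (1.0 + np.exp(-logits))
        labels = np.where(allergic, "allergic", "tolerant")
        ofc.iloc[:n_ofc, ofc.columns.get_loc(fish)] = labels[:n_ofc]

    cohort = CohortTable(sige=sige_df, ofc=ofc)
    truth = CohortTruth(
        analyte_groups=groups, mu=mu, sigma=sigma, rho_within=rho_within,
        rho_between=rho_between, alpha=alpha, beta=beta, latent=latent_df, seed=seed,
    )
    return cohort, truth


def family_outgroups(
    db: list[AllergenRecord],
    family: str = "PV",
    identities: tuple[float, ...] = (0.55, 0.58, 0.62),
    seed: int = 0,
) -> list[SequenceRecord]:
    """Distant homologs of a family for conservation-score reference.

    Emulates non-fish family members (e.g. amphibian and avian
    parvalbumins) by mutating the family founder down to ~55-62%
    identity; such sequences should receive clearly lower conservation
    scores than any core member.
    """
    members = [r for r in db if r.name == family]
    if not members:
        raise ValueError(f"no members of family {family!r} in database")
    rng = np.random.default_rng(seed)
    founder = members[0].seq
    return [
        SequenceRecord(
            id=f"{family}_outgroup{i + 1}", description=f"{family}_outgroup{i + 1}",
            seq=mutate_to_identity(founder, identity, rng),
        )
        for i, identity in enumerate(identities)
    ]


def family_msa(db: list[AllergenRecord], family: str = "PV",
               truth: pd.DataFrame | None = None,
               extra: list[SequenceRecord] | None = None) -> list[SequenceRecord]:
    """Equal-length family members as an (ungapped) alignment.

    Generated family members share their founder's length, so stacking
    them is already a gap-free multiple alignment.  Passing a
    transcriptome ``truth`` table appends the planted homolog proteins
    of the same family (one per transcript), emulating a family
    alignment pooled from the reference database plus the fish
    transcriptomes; ``extra`` appends arbitrary equal-length records.
    """
    members = [SequenceRecord(id=r.id, description=r.id, seq=r.seq)
               for r in db if r.name == family]
    if truth is not None:
        planted = truth[(~truth["is_decoy"]) & (truth["family"] == family)]
        members += [
            SequenceRecord(id=row["transcript_id"], description=row["transcript_id"],
                           seq=row["protein"])
            for _, row in planted.iterrows()
        ]
    if extra:
        members = members + list(extra)
    widths = {len(m.seq) for m in members}
    if len(widths) > 1:
        raise ValueError(f"family {family!r} sequences have unequal lengths {sorted(widths)}")
    return members
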