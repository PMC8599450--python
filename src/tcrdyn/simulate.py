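"""Seeded synthetic cohorts with known clonal-dynamics and genomic truth.

The generator emulates the qualitative structure of longitudinal,
multi-region bulk TCR-seq from checkpoint-inhibitor-treated tumours:

* heavy-tailed baseline clone frequencies (Zipf law);
* a set of truth-expanded clones above the 2/1000 working threshold;
* responder-like patients mostly *maintain* their expanded clones
  after treatment, non-responder-like patients mostly *replace* them
  with novel expanded clones;
* motif-structured CDR3 families whose members share amino-acid
  triplets (within-family spectrum kernel > 0.82 by construction);
* independent multinomial sampling of each tumour region at a fixed
  UMI depth.

Two guard rails keep the generating truth observable after sampling:
maintained clones' post-treatment generating frequency is floored at
1.75x the expansion threshold, and background clones are capped below
it, so threshold-crossing by multinomial noise is negligible at the
default depth.  The genomic generator is the forward model of the
CCF/VAF relation with binomial read noise plus copy-number segments
with a known aberrant fraction.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clustering import triplet_kernel
from .genomics import CCF_GRID, expected_vaf
from .io import POOLED_REGION, Repertoire, SampleMeta

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: generating-frequency floor for maintained clones (1.75x the 2/1000
#: expansion threshold) and cap for background clones (0.75x); see the
#: methods note on why fate truth needs a guard band around the
#: threshold under multinomial sampling
MAINTAINED_FLOOR = 0.0035
BACKGROUND_CAP = 0.0015


class GenerationError(RuntimeError):
    """A sequence-family constraint could not be satisfied."""


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults describe a 15-patient trial-like cohort (4 responders, 11
    non-responders), ~3000 clones per repertoire sampled at 20,000
    UMIs over 2 tumour regions, 30 truth-expanded clones per patient
    and a strong maintenance contrast between response groups.
    """

    n_responders: int = 4
    n_nonresponders: int = 11
    n_clones: int = 3000
    depth: int = 20_000
    n_regions: int = 2
    zipf_exponent: float = 1.3
    n_expanded_truth: int = 30
    maintain_prob_responder: float = 0.8
    maintain_prob_nonresponder: float = 0.2
    lognormal_sigma: float = 0.5
    n_motif_families: int = 5
    family_size: int = 6
    cdr3_len_range: tuple[int, int] = (8, 18)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_expanded_truth > self.n_clones:
            raise ValueError("n_expanded_truth cannot exceed n_clones")
        for name in ("n_responders", "n_nonresponders", "n_clones", "depth", "n_regions"):
            if getattr(self, name) < 1 and name not in ("n_responders", "n_nonresponders"):
                raise ValueError(f"{name} must be positive")
        if self.n_responders + self.n_nonresponders < 1:
            raise ValueError("cohort must contain at least one patient")
        if self.zipf_exponent <= 1.0:
            raise ValueError("zipf_exponent must exceed 1")
        if not (0 <= self.maintain_prob_nonresponder <= 1 and 0 <= self.maintain_prob_responder <= 1):
            raise ValueError("maintenance probabilities must lie in [0, 1]")


@dataclass
class SimulatedCohort:
    repertoires: list[Repertoire]
    truth: pd.DataFrame
    response: dict[str, str]  # patient_id -> responder / nonresponder
    config: CohortConfig

    def patient_repertoires(self, patient_id: str, timepoint: str) -> list[Repertoire]:
        return [
            r
            for r in self.repertoires
            if r.meta.patient_id == patient_id and r.meta.timepoint == timepoint
        ]


def _random_cdr3(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_cdr3_families(
    n_families: int,
    family_size: int,
    background_n: int,
    len_range: tuple[int, int] = (8, 18),
    seed: int | np.random.Generator | None = None,
    max_tries: int = 500,
) -> tuple[list[str], list[int]]:
    """Motif-structured CDR3 families plus uniform-random background.

    Each family mutates at most two positions of a random seed sequence
    and keeps only members whose normalised triplet kernel against every
    accepted member exceeds 0.82 (verified at generation).  Family
    labels are 0..n_families-1; background sequences carry label -1.
    All sequences are unique.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = len_range
    if lo < 3:
        raise ValueError("CDR3 length range must start at >= 3")
    sequences: list[str] = []
    labels: list[int] = []
    seen: set[str] = set()
    fam_lo = max(lo, 12)  # short seeds cannot keep the kernel above 0.82 after mutation
    for fam in range(n_families):
        for attempt in range(max_tries):
            length = int(rng.integers(fam_lo, max(hi, fam_lo) + 1))
            seed_seq = _random_cdr3(rng, length)
            members = [seed_seq]
            tries = 0
            while len(members) < family_size and tries < max_tries:
                tries += 1
                n_mut = int(rng.integers(1, 3))  # mutate 1 or 2 positions
                pos = rng.choice(length, size=n_mut, replace=False)
                cand = list(seed_seq)
                for p in pos:
                    cand[p] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
                cand_s = "".join(cand)
                if cand_s in seen or cand_s in members:
                    continue
                if all(triplet_kernel(cand_s, m) > 0.82 for m in members):
                    members.append(cand_s)
            if len(members) == family_size and seed_seq not in seen:
                sequences.extend(members)
                labels.extend([fam] * family_size)
                seen.update(members)
                break
        else:
            raise GenerationError(
                f"could not build family {fam} satisfying the kernel constraint"
            )
    while len(sequences) < n_families * family_size + background_n:
        length = int(rng.integers(lo, hi + 1))
        s = _random_cdr3(rng, length)
        if s not in seen:
            sequences.append(s)
            labels.append(-1)
            seen.add(s)
    return sequences, labels


def _zipf_frequencies(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def _cap_background(freqs: np.ndarray, cap: float) -> np.ndarray:
    """Water-fill a frequency vector so no entry exceeds ``cap``,
    preserving the total mass."""
    f = freqs.copy()
    total = f.sum()
    for _ in range(100):
        over = f > cap
        if not over.any():
            break
        excess = (f[over] - cap).sum()
        f[over] = cap
        under = ~over
        f[under] += excess * f[under] / f[under].sum()
    return f * (total / f.sum())


def _simulate_patient(
    rng: np.random.Generator, cfg: CohortConfig, patient_id: str, maintain_prob: float
) -> tuple[list[Repertoire], pd.DataFrame]:
    n_fam_seqs = cfg.n_motif_families * cfg.family_size
    n_novel_pool = cfg.n_expanded_truth  # reserve enough for full replacement
    n_bg_seqs = cfg.n_clones + n_novel_pool - n_fam_seqs
    seqs, fam_labels = generate_cdr3_families(
        cfg.n_motif_families, cfg.family_size, n_bg_seqs, cfg.cdr3_len_range, seed=rng
    )
    # clone 0..n_expanded-1: truth expanded (motif-family sequences first,
    # mirroring the observation that expanded clones share CDR3 motifs);
    # the last n_novel_pool sequences are reserved for novel clones
    keys = np.array([f"{patient_id}.C{i:05d}" for i in range(len(seqs))])
    n = cfg.n_clones
    n_exp = cfg.n_expanded_truth

    # expanded generating frequencies: uniform on (0.004, hi) with hi
    # shrunk for large expanded sets so their total mass stays below ~0.6
    exp_hi = min(0.02, max(0.005, 0.7 / n_exp))
    base = np.zeros(len(seqs))
    exp_pre = rng.uniform(0.004, exp_hi, size=n_exp)
    bg_mass = 1.0 - exp_pre.sum()
    if bg_mass <= 0.05:
        raise ValueError("n_expanded_truth too large for the expanded-frequency band")
    bg_shape = _zipf_frequencies(n - n_exp, cfg.zipf_exponent)
    base[:n_exp] = exp_pre
    base[n_exp:n] = _cap_background(bg_shape * bg_mass, BACKGROUND_CAP)
    base /= base.sum()

    maintained = rng.random(n_exp) < maintain_prob
    post = base.copy()
    drift = np.exp(rng.normal(0.0, cfg.lognormal_sigma, size=n_exp))
    post_exp = base[:n_exp] * drift
    post_exp[maintained] = np.maximum(post_exp[maintained], MAINTAINED_FLOOR)
    post_exp[~maintained] = 0.0002  # replaced: detectable only at background level
    post[:n_exp] = post_exp
    # novel expanded clones take over the replaced clones' niche
    novel_idx = np.arange(n, n + int((~maintained).sum()))
    post[novel_idx] = rng.uniform(0.004, exp_hi, size=len(novel_idx))
    post /= post.sum()
    for _ in range(10):  # keep maintained clones safely above threshold after renorm
        low = np.zeros(len(post), dtype=bool)
        low[:n_exp] = maintained & (post[:n_exp] < MAINTAINED_FLOOR)
        if not low.any():
            break
        post[low] = MAINTAINED_FLOOR
        post /= post.sum()

    reps: list[Repertoire] = []
    for tp, freqs in (("pre", base), ("post", post)):
        for region in range(cfg.n_regions):
            counts = rng.multinomial(cfg.depth, freqs)
            nz = counts > 0
            table = pd.DataFrame(
                {
                    "clone_key": keys[nz],
                    "cdr3_aa": np.array(seqs)[nz],
                    "v_call": "TRBV0",
                    "j_call": "TRBJ0",
                    "umi_count": counts[nz],
                }
            )
            meta = SampleMeta(
                patient_id=patient_id,
                timepoint=tp,
                compartment="tumor",
                region_id=f"R{region + 1}",
            )
            reps.append(Repertoire(meta=meta, table=table))
    fate = np.full(len(seqs), "none", dtype=object)
    fate[:n_exp] = np.where(maintained, "maintained", "replaced")
    fate[novel_idx] = "novel"
    truth = pd.DataFrame(
        {
            "patient_id": patient_id,
            "clone_key": keys,
            "cdr3_aa": seqs,
            "family_id": fam_labels,
            "is_expanded_truth": [i < n_exp for i in range(len(seqs))],
            "fate_truth": fate,
            "freq_pre_truth": base,
            "freq_post_truth": post,
        }
    )
    return reps, truth


def simulate_cohort(cfg: CohortConfig = CohortConfig()) -> SimulatedCohort:
    """Generate a full responder/non-responder cohort from one seed.

    Per patient: motif-structured and background CDR3s, Zipf baseline
    frequencies with truth-expanded clones, maintenance/replacement
    post-treatment dynamics, and independent multinomial region samples
    at both timepoints.  Fully reproducible from ``cfg.seed``.
    """
    root = np.random.SeedSequence(cfg.seed)
    patients = [(f"R{i + 1:02d}", "responder") for i in range(cfg.n_responders)] + [
        (f"N{i + 1:02d}", "nonresponder") for i in range(cfg.n_nonresponders)
    ]
    reps: list[Repertoire] = []
    truths = []
    for child, (pid, group) in zip(root.spawn(len(patients)), patients):
        rng = np.random.default_rng(child)
        mp = (
            cfg.maintain_prob_responder
            if group == "responder"
            else cfg.maintain_prob_nonresponder
        )
        p_reps, p_truth = _simulate_patient(rng, cfg, pid, mp)
        reps.extend(p_reps)
        truths.append(p_truth)
    return SimulatedCohort(
        repertoires=reps,
        truth=pd.concat(truths, ignore_index=True),
        response={pid: group for pid, group in patients},
        config=cfg,
    )


def simulate_genomic_sample(
    n_mutations: int,
    purity: float,
    depth: int,
    seed: int | np.random.Generator | None = None,
    clonal_fraction: float = 0.6,
    neoantigen_fraction: float = 0.2,
    aberrant_fraction: float = 0.3,
    ploidy: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Forward-simulate one tumour sample's mutations and CN segments.

    Truth CCF is 1.0 (clonal) with probability ``clonal_fraction``,
    otherwise uniform on the 0.01 grid below 1; the copy-number context
    is drawn from CN_t in {1..4} with CN_mut in {1..CN_t}; observed VAF
    is Binomial(depth, expected VAF)/depth.  Segments place a fraction
    ``aberrant_fraction`` of each autosome at a non-ploidy copy number.
    Returns (mutations, segments, truth) with per-mutation truth values
    inside the mutation table (columns suffixed ``_truth``).
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clonal = rng.random(n_mutations) < clonal_fraction
    ccf = np.where(clonal, 1.0, CCF_GRID[rng.integers(0, 99, size=n_mutations)])
    cn_t = rng.integers(1, 5, size=n_mutations)
    cn_mut = np.array([rng.integers(1, c + 1) for c in cn_t])
    exp_vaf = np.array(
        [expected_vaf(c, m, purity, t) for c, m, t in zip(ccf, cn_mut, cn_t)]
    )
    vaf = rng.binomial(depth, np.clip(exp_vaf, 0, 1)) / depth
    classes = rng.choice(
        ["nsSNV", "fsINDEL", "other"], size=n_mutations, p=[0.8, 0.1, 0.1]
    )
    mutations = pd.DataFrame(
        {
            "mutation_id": [f"M{i:05d}" for i in range(n_mutations)],
            "sample_id": "S1",
            "vaf": vaf,
            "cn_tumor": cn_t,
            "cn_normal": 2,
            "mutation_class": classes,
            "is_exonic": True,
            "is_neoantigen_encoding": rng.random(n_mutations) < neoantigen_fraction,
            "ccf_truth": ccf,
            "cn_mut_truth": cn_mut,
            "depth": depth,
        }
    )
    ref_cn = int(round(ploidy))
    aberrant_cn = ref_cn + 1 if ref_cn < 4 else ref_cn - 1
    seg_rows = []
    chrom_len = 100_000_000
    for chrom in range(1, 23):
        ab_len = int(aberrant_fraction * chrom_len)
        if ab_len > 0:
            seg_rows.append(
                {"chromosome": str(chrom), "start": 0, "end": ab_len, "total_cn": aberrant_cn}
            )
        if ab_len < chrom_len:
            seg_rows.append(
                {
                    "chromosome": str(chrom),
                    "start": ab_len,
                    "end": chrom_len,
                    "total_cn": ref_cn,
                }
            )
    segments = pd.DataFrame(seg_rows)
    truth = {
        "purity": purity,
        "ploidy": ploidy,
        "aberrant_fraction": aberrant_fraction,
        "clonal_fraction": clonal_fraction,
    }
    return mutations, segments, truth


def write_cohort(cohort: SimulatedCohort, out_dir) -> "Path":
    """Write a simulated cohort in the manifest + simple_tsv layout
    that :mod:`tcrdyn.io` reads; returns the manifest path."""
    from pathlib import Path

    from .io import write_repertoire

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rep in cohort.repertoires:
        m = rep.meta
        fname = f"{m.patient_id}_{m.timepoint}_{m.compartment}_{m.region_id}.tsv"
        write_repertoire(rep, out / fname, format="simple_tsv")
        rows.append(
            {
                "patient_id": m.patient_id,
                "timepoint": m.timepoint,
                "compartment": m.compartment,
                "region_id": m.region_id,
                "path": fname,
                "format": "simple_tsv",
            }
        )
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(cohort.response.items()), columns=["patient_id", "response"]
    ).to_csv(out / "response.tsv", sep="\t", index=False)
    return manifest
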