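"""piRNA -> transcript target prediction.

The guide rule: take piRNA positions 2..21 (a 20-nt guide), and report every
20-nt transcript window whose reverse complement lies within a Hamming
distance of 3 (configurable) of the guide — i.e. antisense pairing of the
guide to the mRNA with up to 3 mismatches, gap-free.  The search is
seed-and-extend: the matching pattern is split into four non-overlapping
5-mers, so by pigeonhole any window with <= 3 mismatches contains at least
one exact seed; every seed hit is then verified by direct Hamming count.
The result is exactly the brute-force full scan.
"""
from __future__ import annotations

from typing import Mapping

import pandas as pd

from .simulate import region_of
from .util import hamming, revcomp

SITE_COLUMNS = ["pirna_id", "transcript_id", "start", "end", "mismatches", "region"]
GUIDE_LENGTH = 20
SEED_LENGTH = 5


def extract_guide(pirna_sequence: str) -> tuple[str | None, str]:
    """Guide = piRNA positions 2..21 (1-based); returns (guide, skip reason)."""
    if len(pirna_sequence) < GUIDE_LENGTH + 1:
        return None, "too short for guide (< 21 nt)"
    return pirna_sequence[1 : GUIDE_LENGTH + 1], ""


def extract_guides(pirnas: Mapping[str, str]) -> tuple[dict[str, str], pd.DataFrame]:
    guides: dict[str, str] = {}
    skipped = []
    for pid, seq in pirnas.items():
        guide, reason = extract_guide(seq)
        if guide is None:
            skipped.append({"pirna_id": pid, "length": len(seq), "reason": reason})
        else:
            guides[pid] = guide
    return guides, pd.DataFrame(skipped, columns=["pirna_id", "length", "reason"])


def _seed_index(seq: str, k: int = SEED_LENGTH) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def find_sites(
    guides: Mapping[str, str],
    transcripts: Mapping[str, str],
    transcript_regions: pd.DataFrame | None = None,
    max_mismatches: int = 3,
) -> pd.DataFrame:
    """All qualifying target sites of each guide on each transcript.

    A site is a 20-nt window [start, start+20) such that the Hamming distance
    between the guide and the reverse complement of the window is at most
    ``max_mismatches``; the exact mismatch count is reported.  The region
    label (5'UTR / CDS / 3'UTR) is assigned by the window midpoint when a
    region table (transcript_id, utr5_end, cds_end, length) is given.
    Transcripts shorter than 20 nt are skipped.  For thresholds above 3 the
    4-seed pigeonhole no longer covers, so a full scan is used instead.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    regions = (
        transcript_regions.set_index("transcript_id")
        if transcript_regions is not None
        else None
    )
    use_seeds = max_mismatches <= 3
    rows = []
    for tid in sorted(transcripts):
        tseq = transcripts[tid]
        L = len(tseq)
        if L < GUIDE_LENGTH:
            continue
        seed_idx = _seed_index(tseq) if use_seeds else None
        for pid in sorted(guides):
            pattern = revcomp(guides[pid])  # what a target window must resemble
            if use_seeds:
                starts = set()
                for off in range(0, GUIDE_LENGTH, SEED_LENGTH):
                    for pos in seed_idx.get(pattern[off : off + SEED_LENGTH], ()):
                        s = pos - off
                        if 0 <= s <= L - GUIDE_LENGTH:
                            starts.add(s)
                candidates = sorted(starts)
            else:
                candidates = range(L - GUIDE_LENGTH + 1)
            for s in candidates:
                mm = hamming(tseq[s : s + GUIDE_LENGTH], pattern)
                if mm <= max_mismatches:
                    rec = {
                        "pirna_id": pid,
                        "transcript_id": tid,
                        "start": s,
                        "end": s + GUIDE_LENGTH,
                        "mismatches": mm,
                    }
                    if regions is not None:
                        r = regions.loc[tid]
                        rec["region"] = region_of(
                            s + GUIDE_LENGTH // 2, int(r["utr5_end"]), int(r["cds_end"])
                        )
                    else:
                        rec["region"] = "NA"
                    rows.append(rec)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if len(sites):
        sites = sites.sort_values(
            ["pirna_id", "transcript_id", "start"], ignore_index=True
        )
    return sites


def target_summary(sites: pd.DataFrame) -> dict:
    """Per-region and per-molecule tallies of predicted sites."""
    if sites.empty:
        empty = pd.Series(dtype=int)
        return {
            "n_sites": 0,
            "n_target_transcripts": 0,
            "n_pirnas_with_targets": 0,
            "region_counts": pd.Series(0, index=["five_prime_utr", "CDS", "three_prime_utr"]),
            "targets_per_pirna": empty,
            "pirnas_per_target": empty,
            "pair_site_counts": pd.DataFrame(columns=["pirna_id", "transcript_id", "n_sites"]),
            "max_pirnas_per_target": 0,
            "max_sites_per_pair": 0,
        }
    region_counts = (
        sites["region"].value_counts()
        .reindex(["five_prime_utr", "CDS", "three_prime_utr"], fill_value=0)
    )
    targets_per_pirna = sites.groupby("pirna_id")["transcript_id"].nunique()
    pirnas_per_target = sites.groupby("transcript_id")["pirna_id"].nunique()
    pair_site_counts = (
        sites.groupby(["pirna_id", "transcript_id"]).size().rename("n_sites").reset_index()
    )
    return {
        "n_sites": int(len(sites)),
        "n_target_transcripts": int(sites["transcript_id"].nunique()),
        "n_pirnas_with_targets": int(sites["pirna_id"].nunique()),
        "region_counts": region_counts,
        "targets_per_pirna": targets_per_pirna,
        "pirnas_per_target": pirnas_per_target,
        "pair_site_counts": pair_site_counts,
        "max_pirnas_per_target": int(pirnas_per_target.max()),
        "max_sites_per_pair": int(pair_site_counts["n_sites"].max()),
    }
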