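"""Tabular (TSV) export of sites, counts, calls, and evidence.

All genomic positions in exported tables are 1-based inclusive; the
in-memory representation is 0-based half-open.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import pandas as pd

from rsdetect.intermediates import CrypticExonCall
from rsdetect.junctions import SiteJunctionCounts
from rsdetect.motif_scan import MotifSite
from rsdetect.rs_caller import RSCall


def sites_table(sites: Iterable[MotifSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        lo, hi = s.ref_interval
        rows.append({
            "chrom": s.chrom, "start": lo + 1, "end": hi, "motif": s.motif,
            "gene_id": s.gene_id, "strand": s.strand,
            "intron_ordinal": s.intron_ordinal,
            "intron_length": s.intron_length,
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "motif",
                                       "gene_id", "strand", "intron_ordinal",
                                       "intron_length"])


def counts_table(site_counts: Mapping[str, SiteJunctionCounts]) -> pd.DataFrame:
    rows = []
    for site_id, c in site_counts.items():
        samples = sorted(set(c.up_count) | set(c.down_count))
        for sample in samples:
            rows.append({
                "site_id": site_id, "sample": sample,
                "up_count": c.up_count.get(sample, 0),
                "up_rpm": c.up_rpm.get(sample, 0.0),
                "down_count": c.down_count.get(sample, 0),
                "down_rpm": c.down_rpm.get(sample, 0.0),
                "down_donor_pos": (None if c.down_donor_pos is None
                                   else c.down_donor_pos + 1),
            })
    return pd.DataFrame(rows, columns=["site_id", "sample", "up_count",
                                       "up_rpm", "down_count", "down_rpm",
                                       "down_donor_pos"])


def _fmt_fold(x: float) -> str:
    return "inf" if math.isinf(x) else f"{x:.6g}"


def calls_table(calls: Iterable[RSCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        s = c.site
        rows.append({
            "site_id": s.site_id, "gene_id": s.gene_id, "chrom": s.chrom,
            "pos": s.a_pos + 1, "strand": s.strand, "motif": s.motif,
            "intron_ordinal": s.intron_ordinal, "intron_len": s.intron_length,
            "merged_count": c.merged_up_count,
            "total_rpm": round(c.total_rpm, 6),
            "mrna_rpm": round(c.mrna_rpm, 6),
            "fold": _fmt_fold(c.fold_enrichment),
            "sawtooth_score": round(c.sawtooth_score, 4),
            "exon_score": round(c.exon_score, 4),
            "classification": c.classification,
        })
    return pd.DataFrame(rows, columns=[
        "site_id", "gene_id", "chrom", "pos", "strand", "motif",
        "intron_ordinal", "intron_len", "merged_count", "total_rpm",
        "mrna_rpm", "fold", "sawtooth_score", "exon_score", "classification"])


def cryptic_table(calls: Iterable[CrypticExonCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        s = c.site
        rows.append({
            "site_id": s.site_id, "gene_id": s.gene_id, "chrom": s.chrom,
            "pos": s.a_pos + 1, "strand": s.strand,
            "intron_len": s.intron_length,
            "up_count": c.merged_up_count, "down_count": c.merged_down_count,
            "exon_start": c.exon_start + 1,
            "exon_end": (None if c.exon_end_donor is None
                         else c.exon_end_donor + 1),
            "sawtooth_score": round(c.sawtooth_score, 4),
            "exon_score": round(c.exon_score, 4),
            "classification": c.classification,
        })
    return pd.DataFrame(rows, columns=[
        "site_id", "gene_id", "chrom", "pos", "strand", "intron_len",
        "up_count", "down_count", "exon_start", "exon_end",
        "sawtooth_score", "exon_score", "classification"])


def evidence_table(evidence: Mapping) -> pd.DataFrame:
    rows = []
    for site_id, ev in evidence.items():
        saw = ev.sawtooth
        rows.append({
            "site_id": site_id, "w_up": saw.w_up, "w_down": saw.w_down,
            "up_mean": round(saw.up_mean, 4),
            "down_mean": round(saw.down_mean, 4),
            "sawtooth_score": round(saw.score, 4),
            "trend_up_rho": round(saw.rho_up, 4),
            "trend_down_rho": round(saw.rho_down, 4),
            "exon_score": round(ev.exon_score, 4),
            "trend_ok": saw.trend_ok,
        })
    return pd.DataFrame(rows, columns=[
        "site_id", "w_up", "w_down", "up_mean", "down_mean",
        "sawtooth_score", "trend_up_rho", "trend_down_rho", "exon_score",
        "trend_ok"])


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
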