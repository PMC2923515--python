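"""Publication-style analysis reports: identity matrices, conservation
grids, topology strings, and partition summaries.

The identity matrix mirrors the classic ferlin C2-domain comparison: each
protein's named C2 domains are globally aligned to the corresponding C2 of a
reference ferlin of the same type (a Type 1 reference for Type 1 rows, Type
2 for Type 2 rows), reporting percent identity per cell, blank where either
side lacks that domain.
"""

from __future__ import annotations

import pandas as pd

from .align import AlignParams, percent_identity
from .calcium import AnchorSet, conservation_table
from .library import is_c2_name
from .scan import Architecture

C2_COLUMNS = ("C2A", "C2B", "C2C", "C2D", "C2DE", "C2E", "C2F")


def _c2_sequences(protein: str, arch: Architecture) -> dict[str, str]:
    return {
        h.domain_name: protein[h.start : h.end]
        for h in arch.hits
        if is_c2_name(h.domain_name) and h.domain_name in C2_COLUMNS
    }


def identity_matrix(
    proteins: dict[str, str],
    architectures: dict[str, Architecture],
    reference_ids: dict[int, str],
    params: AlignParams | None = None,
) -> pd.DataFrame:
    """Percent identity of each C2 domain vs the same-type reference ferlin.

    ``reference_ids`` maps ferlin type (1/2) to the reference protein id.
    Reference rows are omitted; proteins of unknown type are skipped.
    """
    params = params or AlignParams()
    ref_c2: dict[int, dict[str, str]] = {}
    for ftype, rid in reference_ids.items():
        ref_c2[ftype] = _c2_sequences(proteins[rid], architectures[rid])
    rows = {}
    for pid, seq in proteins.items():
        arch = architectures[pid]
        if arch.ferlin_type not in ref_c2 or pid in reference_ids.values():
            continue
        own = _c2_sequences(seq, arch)
        ref = ref_c2[arch.ferlin_type]
        row = {}
        for c2 in C2_COLUMNS:
            if c2 in own and c2 in ref:
                row[c2] = percent_identity(own[c2], ref[c2], params)
            else:
                row[c2] = float("nan")
        rows[pid] = row
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(C2_COLUMNS))
    out.index.name = "ferlin"
    types = [architectures[pid].ferlin_type for pid in out.index]
    out.insert(0, "type", types)
    return out


def topology_report(architectures: dict[str, Architecture]) -> pd.DataFrame:
    """One row per protein: type, subtype, minimal-ferlin flag, topology."""
    rows = []
    for pid, arch in architectures.items():
        rows.append(
            {
                "protein_id": pid,
                "ferlin_type": arch.ferlin_type if arch.ferlin_type else "none",
                "subtype": arch.subtype,
                "minimal_ferlin": arch.is_minimal_ferlin,
                "partial_dysf": arch.partial_dysf,
                "topology": arch.topology_string(),
                "n_marginal_hits": sum(h.marginal for h in arch.hits),
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")


def architecture_table(architectures: dict[str, Architecture]) -> pd.DataFrame:
    """One row per domain hit across all proteins."""
    rows = []
    for pid, arch in architectures.items():
        for h in arch.hits:
            rows.append(
                {
                    "protein_id": pid,
                    "domain": h.domain_name,
                    "start": h.start,
                    "end": h.end,
                    "score": round(h.score, 1),
                    "normalized_score": round(h.normalized_score, 3),
                    "tier": "confident" if h.confident else "marginal",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "domain", "start", "end",
            "score", "normalized_score", "tier",
        ],
    )


def conservation_report(
    proteins: dict[str, str],
    architectures: dict[str, Architecture],
    anchors: AnchorSet | None = None,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    return conservation_table(proteins, architectures, anchors, groups)


def partition_report(report: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "clean_bipartition": report["clean"],
                "support": report["support"],
                "outliers": ";".join(report["outliers"]) if report["outliers"] else "",
            }
        ]
    )
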