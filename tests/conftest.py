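from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from radvar.io_tables import OccurrenceChart, SpecimenMeta, parse_lineage
from radvar.synthetic_data import generate_dataset, paper_like_config

POLY_LINEAGES = {
    "Collosphaeridae": "Eukaryota;TSAR;Rhizaria;Polycystinea;Collodaria;Collosphaeridae;Collosphaera;Collosphaera_huxleyi",
    "Sphaerozoidae": "Eukaryota;TSAR;Rhizaria;Polycystinea;Collodaria;Sphaerozoidae;Sphaerozoum;Sphaerozoum_sp",
    "Pterocorythidae": "Eukaryota;TSAR;Rhizaria;Polycystinea;Nassellaria;Pterocorythidae;Pterocorys;Pterocorys_zancleus",
}


def make_chart(
    counts: dict[str, dict[str, int]],
    families: dict[str, str] | None = None,
    sequences: dict[str, str] | None = None,
    confidence: dict[str, float] | None = None,
) -> OccurrenceChart:
    """Build a chart from {asv: {specimen: count}} with sensible defaults."""
    asvs = sorted(counts)
    specimens = sorted({s for row in counts.values() for s in row})
    matrix = pd.DataFrame(
        0, index=pd.Index(asvs, name="asv_id"), columns=specimens, dtype=np.int64
    )
    for a, row in counts.items():
        for s, c in row.items():
            matrix.at[a, s] = c
    families = families or {}
    rng = np.random.default_rng(0)
    seqs = sequences or {}
    return OccurrenceChart(
        counts=matrix,
        sequences={a: seqs.get(a, "".join(rng.choice(list("ACGT"), 60))) for a in asvs},
        lineage={
            a: parse_lineage(POLY_LINEAGES.get(families.get(a, "Collosphaeridae"),
                                               POLY_LINEAGES["Collosphaeridae"]))
            if families.get(a, "Collosphaeridae") in POLY_LINEAGES
            else parse_lineage(
                f"Eukaryota;TSAR;Rhizaria;Polycystinea;Collodaria;{families[a]};G;S"
            )
            for a in asvs
        },
        confidence={a: (confidence or {}).get(a, 0.95) for a in asvs},
    )


def make_meta(
    specimens: list[str],
    family: str = "Collosphaeridae",
    order: str = "Collodaria",
    morphotaxon: str = "Collosphaera huxleyi",
    relaxed: dict[str, bool] | None = None,
) -> dict[str, SpecimenMeta]:
    relaxed = relaxed or {}
    return {
        s: SpecimenMeta(
            specimen_id=s,
            morphotaxon=morphotaxon,
            morph_rank="indeterminate" if relaxed.get(s) else "species",
            order_name=order,
            family_name="unknown" if relaxed.get(s) else family,
            relaxed_filter=relaxed.get(s, False),
        )
        for s in specimens
    }


@pytest.fixture(scope="session")
def paper_like_bundle():
    """A small paper-like synthetic dataset shared by read-only tests."""
    cfg = paper_like_config(seed=1, scale=0.5)
    return generate_dataset(cfg)
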