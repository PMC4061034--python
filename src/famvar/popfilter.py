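"""The ordered population-database exclusion cascade.

Variants documented in dbSNP, the 1000 Genomes panel or HapMap with an
allele frequency above 0.5 % are rejected; the YH personal genome carries
no population frequency, so mere presence there rejects. Variants without
a record in a database are treated as absent (retained). The final
survivor set is order-invariant; only the intermediate per-stage counts
depend on the database order, which is why the order is configurable but
cosmetic.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

from .core import PopulationRecord, QCThresholds

logger = logging.getLogger("famvar")

DEFAULT_ORDER = ("dbSNP", "KG1000", "HapMap", "YH")

#: databases that reject on presence alone (no usable allele frequency)
PRESENCE_REJECT_DBS = frozenset({"YH"})


def reject_by_database(variant_key: str, record: Optional[PopulationRecord],
                       threshold: float = 0.005) -> bool:
    """True if the variant is rejected by this database record.

    Frequency databases reject iff present with a KNOWN frequency strictly
    above ``threshold``; YH rejects on presence alone. A present record
    with unknown frequency in a frequency database is indeterminate and
    retained (logged).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    if record is None or not record.present:
        return False
    if record.db in PRESENCE_REJECT_DBS:
        return True
    if record.af is None:
        logger.info("%s present in %s with unknown frequency: retained as "
                    "indeterminate", variant_key, record.db)
        return False
    return record.af > threshold


def run_cascade(variants_per_sample: Mapping[str, Sequence[str]],
                db_records: Mapping[str, Mapping[str, PopulationRecord]],
                order: Sequence[str] = DEFAULT_ORDER,
                threshold: float = 0.005,
                ) -> tuple[dict[str, list[str]],
                           list[tuple[str, dict[str, int]]]]:
    """Apply the database rejections sequentially.

    ``variants_per_sample`` maps a stream name (sample id) to variant keys;
    ``db_records`` maps variant key -> {db name: PopulationRecord}.
    Returns (survivors per stream, [(stage label, counts per stream)]).
    """
    if len(set(order)) != len(order):
        raise ValueError("database order contains duplicates")
    current = {s: list(keys) for s, keys in variants_per_sample.items()}
    stages: list[tuple[str, dict[str, int]]] = []
    label_parts: list[str] = []
    for db in order:
        label_parts.append(db)
        for stream, keys in current.items():
            current[stream] = [
                k for k in keys
                if not reject_by_database(k, db_records.get(k, {}).get(db),
                                          threshold)]
        stages.append((f"after filtering against {'+'.join(label_parts)}",
                       {s: len(keys) for s, keys in current.items()}))
    return current, stages


def cascade_survivors(keys: Sequence[str],
                      db_records: Mapping[str, Mapping[str, PopulationRecord]],
                      order: Sequence[str] = DEFAULT_ORDER,
                      threshold: float = 0.005) -> list[str]:
    """Order-free survivor set of the full cascade for one variant list."""
    return [k for k in keys
            if not any(reject_by_database(k, db_records.get(k, {}).get(db),
                                          threshold)
                       for db in order)]
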