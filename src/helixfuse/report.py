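"""Per-candidate, per-stage screening reports serialized as TSV and JSON."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Recorded in every report so the RMSD atom convention is auditable.
HEADER_META = {"main_chain_atoms": "N,CA,C,O", "units": "Angstrom"}

COLUMNS = ["label", "stage", "passed", "rmsd", "clash_count", "score", "mean_traj_rmsd", "reason"]


@dataclass
class ScreenReport:
    """Accumulates one record per (candidate, stage).

    Duplicate (label, stage) entries are rejected so every candidate entering
    a stage carries exactly one verdict for it.
    """

    records: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=lambda: dict(HEADER_META))

    def add(
        self,
        label: str,
        stage: str,
        passed: bool,
        reason: str = "",
        **metrics,
    ) -> None:
        key = (label, stage)
        if any((r["label"], r["stage"]) == key for r in self.records):
            raise ValueError(f"duplicate record for candidate {label!r} at stage {stage!r}")
        rec = {"label": label, "stage": stage, "passed": bool(passed), "reason": reason}
        rec.update({k: metrics.get(k) for k in ("rmsd", "clash_count", "score", "mean_traj_rmsd")})
        extra = set(metrics) - {"rmsd", "clash_count", "score", "mean_traj_rmsd"}
        if extra:
            raise ValueError(f"unknown metric fields: {sorted(extra)}")
        self.records.append(rec)

    def extend(self, other: "ScreenReport") -> None:
        for rec in other.records:
            self.add(**rec)

    def for_stage(self, stage: str) -> list[dict]:
        return [r for r in self.records if r["stage"] == stage]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=COLUMNS)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            for k, v in sorted(self.meta.items()):
                fh.write(f"# {k}={v}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    def to_json(self, path: str | Path) -> None:
        payload = {"meta": self.meta, "records": self.records}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=float) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScreenReport":
        payload = json.loads(Path(path).read_text())
        rep = cls(meta=payload["meta"])
        for rec in payload["records"]:
            rep.records.append(rec)
        return rep
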