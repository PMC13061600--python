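"""Reading and writing session logs and run configurations.

Sessions round-trip as a trial-level CSV (one row per trial) plus a JSON
sidecar carrying the game spec, block opponent metadata and seeds.  Payoffs
are validated against the game's payoff matrix on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .game import GameSpec, build_payoff_matrix
from .sessions import BlockRecord, SessionLog

__all__ = ["write_session", "read_session", "load_config", "sessions_to_frame"]

CSV_COLUMNS = [
    "participant",
    "block",
    "trial",
    "action_self",
    "action_opp",
    "payoff_self",
    "payoff_opp",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def sessions_to_frame(log: SessionLog) -> pd.DataFrame:
    rows = []
    for b_idx, block in enumerate(log.blocks):
        for t in range(block.n_trials):
            rows.append(
                {
                    "participant": log.participant,
                    "block": b_idx,
                    "trial": t,
                    "action_self": int(block.actions_self[t]),
                    "action_opp": int(block.actions_opp[t]),
                    "payoff_self": float(block.payoffs_self[t]),
                    "payoff_opp": float(block.payoffs_opp[t]),
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_session(log: SessionLog, path: str | Path) -> None:
    """Write a session as CSV plus a ``.json`` sidecar next to it."""
    path = Path(path)
    sessions_to_frame(log).to_csv(path, index=False)
    sidecar = {
        "participant": log.participant,
        "seed": log.seed,
        "game": {
            "n_actions": log.game.n_actions,
            "zero_sum": log.game.zero_sum,
            "variant_label": log.game.variant_label,
            "nonzero_sum_payoffs": list(log.game.nonzero_sum_payoffs),
        },
        "blocks": [{"opponent": b.opponent} for b in log.blocks],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_session(path: str | Path) -> SessionLog:
    """Read a session CSV (+ JSON sidecar), validating schema and payoffs."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sidecar = json.loads(_sidecar_path(path).read_text())
    g = sidecar["game"]
    game = GameSpec(
        n_actions=g["n_actions"],
        zero_sum=g["zero_sum"],
        variant_label=g.get("variant_label", ""),
        nonzero_sum_payoffs=tuple(g.get("nonzero_sum_payoffs", (1.0, 0.0, 0.0))),
    )
    pi = build_payoff_matrix(game).entries
    n = game.n_actions
    block_meta = sidecar.get("blocks", [])
    blocks = []
    for b_idx, g_df in df.groupby("block", sort=True):
        a_s = g_df["action_self"].to_numpy(int)
        a_o = g_df["action_opp"].to_numpy(int)
        bad = np.where((a_s < 0) | (a_s >= n) | (a_o < 0) | (a_o >= n))[0]
        if len(bad):
            row = g_df.index[bad[0]]
            raise ValueError(
                f"{path}: action out of range for {n}-action game at row {row}"
            )
        p_s = g_df["payoff_self"].to_numpy(float)
        p_o = g_df["payoff_opp"].to_numpy(float)
        mism = np.where(
            (p_s != pi[a_s, a_o]) | (p_o != pi[a_o, a_s])
        )[0]
        if len(mism):
            t = int(g_df["trial"].iloc[mism[0]])
            raise ValueError(
                f"{path}: payoff inconsistent with the payoff matrix in block "
                f"{b_idx}, trial {t}"
            )
        opponent = (
            block_meta[int(b_idx)].get("opponent", {})
            if int(b_idx) < len(block_meta)
            else {}
        )
        blocks.append(
            BlockRecord(
                actions_self=a_s,
                actions_opp=a_o,
                payoffs_self=p_s,
                payoffs_opp=p_o,
                opponent=opponent,
            )
        )
    participant = str(df["participant"].iloc[0])
    return SessionLog(
        participant=participant,
        game=game,
        blocks=blocks,
        seed=sidecar.get("seed"),
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)
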