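"""Scheduled observation and manipulation commands.

Commands are the "virtual experimenter": they execute after the dynamics
substeps of the step in which they fall due, either once (``at t``),
repeatedly (``every dt from t1 to t2``), or at the end of the run (``end``).
Observation commands append one row to a tab-delimited output table; counts
are exact (no sampling).  Numbers are printed with 6 significant digits and
times with 12, so output files are byte-stable for a given (config, seed).
"""

from __future__ import annotations

import numpy as np

from .model import SOLUTION, STATE_NAMES, STATE_INDEX


class OutputTable:
    """Tab-delimited table: a header line naming the observables, then one
    row per scheduled command execution, strictly time-ordered."""

    def __init__(self, name: str, header):
        self.name = name
        self.header = list(header)
        self.rows: list[list] = []

    def append(self, row):
        self.rows.append(list(row))

    @property
    def times(self):
        return np.array([r[0] for r in self.rows], dtype=float)

    def column(self, name):
        j = self.header.index(name)
        return np.array([r[j] for r in self.rows], dtype=float)

    def to_text(self) -> str:
        def fmt(v):
            if isinstance(v, (int, np.integer)):
                return str(int(v))
            return f"{float(v):.6g}"

        lines = ["\t".join(self.header)]
        for row in self.rows:
            cells = [f"{float(row[0]):.12g}"] + [fmt(v) for v in row[1:]]
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"

    def write(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_text())


class ScheduledCommand:
    def __init__(self, spec, sim):
        self.timing = spec["timing"]
        self.action = spec["action"]
        self.args = list(spec["args"])
        self.target = spec["target"]
        if self.timing[0] == "at":
            self.next_due = self.timing[1]
            self.last = self.timing[1]
        elif self.timing[0] == "every":
            _, dt, t1, t2 = self.timing
            self.next_due = t1
            self.last = t2
        else:
            self.next_due = np.inf
            self.last = np.inf
        self._msd_ref: dict | None = None

    def _due(self, t, dt):
        tol = 1e-9 * max(dt, 1e-30)
        return self.next_due <= t + tol and self.next_due <= self.last + tol

    def maybe_run(self, sim):
        while self._due(sim.t, sim.dt):
            self.execute(sim)
            if self.timing[0] == "every":
                self.next_due += self.timing[1]
            else:
                self.next_due = np.inf

    def finish(self, sim):
        if self.timing[0] == "end":
            self.execute(sim)

    # -- actions ------------------------------------------------------------
    def execute(self, sim):
        getattr(self, "_do_" + self.action)(sim)

    def _table(self, sim, header):
        if self.target not in sim.outputs:
            sim.outputs[self.target] = OutputTable(self.target, header)
        return sim.outputs[self.target]

    def _do_molcount(self, sim):
        tab = self._table(sim, ["time"] + sim.species_names)
        tab.append([sim.t] + list(cmd_molcount(sim)))

    def _do_molcount_in_compartment(self, sim):
        comp = sim.compartments[self.args[0]]
        tab = self._table(sim, ["time"] + sim.species_names)
        tab.append([sim.t] + list(cmd_molcount(sim, scope=("compartment",
                                                           comp))))

    def _do_listmols(self, sim):
        tab = self._table(sim, ["time", "serial", "species", "state",
                                "x", "y", "z"])
        store = sim.store
        for i in store.alive_idx():
            tab.append([sim.t, int(store.serial[i]),
                        sim.species_names[store.species[i]],
                        STATE_NAMES[store.state[i]],
                        store.pos[i, 0], store.pos[i, 1], store.pos[i, 2]])

    def _do_meansqrdisp(self, sim):
        sp = sim.species_index[self.args[0]]
        store = sim.store
        idx = np.flatnonzero(store.alive[: store.n]
                             & (store.species[: store.n] == sp))
        upos = sim.unwrapped_pos(idx)
        if self._msd_ref is None:
            self._msd_ref = dict(zip(store.serial[idx].tolist(),
                                     upos.tolist()))
        refs = self._msd_ref
        keep = [i for i, s in enumerate(store.serial[idx].tolist())
                if s in refs]
        tab = self._table(sim, ["time", "msd", "n"])
        if not keep:
            tab.append([sim.t, 0.0, 0])
            return
        cur = upos[keep]
        ref = np.array([refs[int(store.serial[idx[i]])] for i in keep])
        msd = float(np.mean(np.sum((cur - ref) ** 2, axis=1)))
        tab.append([sim.t, msd, len(keep)])

    def _do_set_surface_action(self, sim):
        sname, sp, side, action = self.args
        surf = next(s for s in sim.surfaces if s.name == sname)
        sides = ("front", "back") if side == "both" else (side,)
        for s in sides:
            surf.actions[(sp, s)] = action

    def _do_add_surface(self, sim):
        surf = next(s for s in sim.surfaces if s.name == self.args[0])
        surf.enabled = True

    def _do_add_molecules(self, sim):
        count, sp = int(self.args[0]), self.args[1]
        spi = sim.species_index[sp]
        rest = self.args[2:]
        if not rest or rest[0] == "uniform":
            pos = sim.sample_uniform(count, None, sim.rng)
        else:
            pt = np.zeros(3)
            pt[: len(rest)] = [float(v) for v in rest]
            pos = np.tile(pt, (count, 1))
        sim.store.add(count, spi, SOLUTION, pos, used=True)

    def _do_kill_molecules_in_region(self, sim):
        sp = sim.species_index[self.args[0]]
        comp = sim.compartments[self.args[1]]
        store = sim.store
        idx = np.flatnonzero(store.alive[: store.n]
                             & (store.species[: store.n] == sp))
        if len(idx):
            inside = comp.contains(store.pos[idx])
            store.kill(idx[inside])


def cmd_molcount(sim, scope=None):
    """Counts per species at the current time.

    ``scope`` is ``None`` (whole system), ``('compartment', c)``, or
    ``('surface_state', state_name)`` for surface-bound tallies.
    """
    store = sim.store
    idx = store.alive_idx()
    if scope is not None:
        kind, obj = scope
        if kind == "compartment":
            idx = idx[obj.contains(store.pos[idx])]
        elif kind == "surface_state":
            idx = idx[store.state[idx] == STATE_INDEX[obj]]
        else:
            raise ValueError(f"unknown molcount scope {kind}")
    counts = np.bincount(store.species[idx], minlength=len(sim.species_names))
    return counts


def compile_commands(config, sim):
    return [ScheduledCommand(spec, sim) for spec in config.commands]


def save_outputs(sim, out_dir):
    import os

    os.makedirs(out_dir, exist_ok=True)
    for name, tab in sim.outputs.items():
        tab.write(os.path.join(out_dir, name))
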