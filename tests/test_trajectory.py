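"""Trajectory loading, windows, and the selection grammar."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trrdf
from trrdf import (
    EmptySelectionError,
    SelectionError,
    Trajectory,
    TopologyError,
    WindowScheme,
    load_trajectory,
    partition_windows,
    read_index_file,
    resolve_selection,
)
from trrdf.errors import FormatError
from trrdf.fixtures import generate_ideal_gas, write_gro_xtc


class TestLoading:
    def test_json_round_trip_is_bit_exact(self, small_gas, tmp_path):
        path = tmp_path / "traj.json"
        small_gas.save_json(path)
        back = load_trajectory(path)
        assert np.array_equal(back.xyz, small_gas.xyz)
        assert np.array_equal(back.time, small_gas.time)
        assert np.array_equal(back.cells, small_gas.cells)
        assert back.topology.equals(small_gas.topology)

    def test_gro_xtc_round_trip_within_format_precision(self, small_gas, tmp_path):
        gro, xtc = write_gro_xtc(small_gas, tmp_path / "fix")
        back = load_trajectory(xtc, gro)
        assert back.n_frames == small_gas.n_frames
        assert back.n_atoms == small_gas.n_atoms
        # XTC stores single precision, quantized to ~1e-3 nm
        assert np.abs(back.xyz - small_gas.xyz).max() < 2e-3
        assert np.abs(back.cells - small_gas.cells).max() < 1e-5
        assert list(back.topology["resname"].unique()) == ["GAS"]

    def test_mdtraj_reader_agrees_with_independent_writer(self, tmp_path):
        """Write a 4-atom system with MDTraj itself; our loader must agree."""
        import mdtraj as md

        top = md.Topology()
        ch = top.add_chain()
        res = top.add_residue("UNK", ch)
        for i in range(4):
            top.add_atom(f"C{i}", md.element.carbon, res)
        rng = np.random.default_rng(11)
        xyz = rng.random((3, 4, 3)).astype(np.float32)
        ref = md.Trajectory(xyz=xyz, topology=top, time=np.arange(3, dtype=float))
        ref.unitcell_vectors = np.tile(np.eye(3, dtype=np.float32) * 5.0, (3, 1, 1))
        ref[0].save_gro(str(tmp_path / "w.gro"))
        ref.save_xtc(str(tmp_path / "w.xtc"))
        ours = load_trajectory(tmp_path / "w.xtc", tmp_path / "w.gro")
        assert np.abs(ours.xyz - xyz).max() < 1e-3

    def test_stride_keeps_every_other_frame(self, tmp_path):
        traj = generate_ideal_gas(4, 10, 3.0, seed=0)
        path = tmp_path / "t.json"
        traj.save_json(path)
        strided = load_trajectory(path, stride=2)
        assert strided.n_frames == 5
        assert np.array_equal(strided.xyz, traj.xyz[::2])

    def test_missing_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            load_trajectory(tmp_path / "nope.xtc")

    def test_atom_count_mismatch_is_topology_error(self, small_gas, tmp_path):
        other = generate_ideal_gas(5, 2, 4.0, seed=1)
        gro, _ = write_gro_xtc(other, tmp_path / "top5")
        _, xtc = write_gro_xtc(small_gas, tmp_path / "traj8")
        with pytest.raises((TopologyError, FormatError)):
            load_trajectory(xtc, gro)

    def test_constant_cell_broadcast(self, small_gas):
        t = Trajectory(
            xyz=small_gas.xyz,
            time=small_gas.time,
            cells=np.eye(3) * 4.0,
            topology=small_gas.topology,
        )
        assert t.cells.shape == (small_gas.n_frames, 3, 3)

    def test_non_monotonic_times_rejected(self, small_gas):
        with pytest.raises(TopologyError):
            Trajectory(
                xyz=small_gas.xyz,
                time=np.zeros(small_gas.n_frames),
                cells=small_gas.cells,
                topology=small_gas.topology,
            )


class TestWindows:
    @pytest.mark.parametrize(
        "n_frames, fpw, policy, expected",
        [
            (10, 5, "drop", [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]),
            (10, 4, "drop", [[0, 1, 2, 3], [4, 5, 6, 7]]),
            (10, 4, "keep-partial", [[0, 1, 2, 3], [4, 5, 6, 7], [8, 9]]),
            (3, 1, "drop", [[0], [1], [2]]),
        ],
    )
    def test_partition_layouts(self, n_frames, fpw, policy, expected):
        windows = partition_windows(n_frames, WindowScheme(fpw, policy=policy))
        assert [w.frames.tolist() for w in windows] == expected

    def test_partial_flagging(self):
        windows = partition_windows(10, WindowScheme(4, policy="keep-partial"))
        assert [w.partial for w in windows] == [False, False, True]

    def test_stride_then_window(self):
        windows = partition_windows(10, WindowScheme(2, stride=3))
        assert [w.frames.tolist() for w in windows] == [[0, 3], [6, 9]]

    def test_oversized_window_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            windows = partition_windows(3, WindowScheme(5))
        assert windows == []

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n_frames=st.integers(1, 200),
        fpw=st.integers(1, 50),
        stride=st.integers(1, 5),
    )
    def test_windows_disjoint_and_tile_strided_range(self, n_frames, fpw, stride):
        windows = partition_windows(
            n_frames, WindowScheme(fpw, stride=stride, policy="drop")
        )
        frames = np.concatenate([w.frames for w in windows]) if windows else np.array([])
        assert len(frames) == len(set(frames.tolist()))  # pairwise disjoint
        n_used = len(range(0, n_frames, stride))
        assert len(frames) == (n_used // fpw) * fpw
        assert np.all(np.diff(frames) > 0)  # time order preserved


def _brute_select(topo: pd.DataFrame, **preds) -> set:
    keep = set(range(len(topo)))
    for col, vals in preds.items():
        keep &= {i for i in range(len(topo)) if topo.iloc[i][col] in vals}
    return keep


class TestSelection:
    def test_name_match(self, tripeptide_topology):
        idx = resolve_selection(tripeptide_topology, "name CL")
        assert list(idx) == [17]

    def test_resid_range_and_element(self, tripeptide_topology):
        idx = resolve_selection(tripeptide_topology, "resid 0 to 2 and element C")
        brute = sorted(
            i
            for i in range(len(tripeptide_topology))
            if tripeptide_topology.iloc[i]["resid"] in (0, 1, 2)
            and tripeptide_topology.iloc[i]["element"] == "C"
        )
        assert list(idx) == brute

    def test_boolean_composition_matches_brute_force(self, tripeptide_topology):
        idx = resolve_selection(
            tripeptide_topology, "(name NA or name CL) and not resid 0"
        )
        brute = sorted(
            i
            for i in range(len(tripeptide_topology))
            if tripeptide_topology.iloc[i]["name"] in ("NA", "CL")
            and tripeptide_topology.iloc[i]["resid"] != 0
        )
        assert list(idx) == brute

    def test_multi_value_keyword_is_implicit_or(self, tripeptide_topology):
        a = resolve_selection(tripeptide_topology, "name NA CL")
        b = resolve_selection(tripeptide_topology, "name NA or name CL")
        assert np.array_equal(a, b)

    def test_raw_index_list(self, tripeptide_topology):
        idx = resolve_selection(tripeptide_topology, [5, 3, 3, 1])
        assert list(idx) == [1, 3, 5]

    def test_empty_selection_is_loud(self, tripeptide_topology):
        with pytest.raises(EmptySelectionError):
            resolve_selection(tripeptide_topology, "name XYZZY")

    @pytest.mark.parametrize(
        "expr", ["", "name", "and name CA", "(name CA", "resid x", "frobnicate CA"]
    )
    def test_syntax_errors(self, tripeptide_topology, expr):
        with pytest.raises(SelectionError):
            resolve_selection(tripeptide_topology, expr)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_random_expressions_match_brute_force(self, seed):
        """Random topologies + random grammar trees vs row-by-row filtering."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        topo = pd.DataFrame(
            {
                "name": rng.choice(["CA", "CB", "NA", "CL", "OW"], n),
                "element": rng.choice(["C", "N", "Na", "Cl", "O"], n),
                "resname": rng.choice(["ALA", "GLY", "SOL"], n),
                "resid": rng.integers(0, 5, n),
                "chain": rng.integers(0, 2, n),
            }
        )

        def leaf():
            kind = rng.choice(["name", "resname", "element", "resid", "chainid"])
            if kind == "resid":
                lo = int(rng.integers(0, 5))
                hi = int(rng.integers(lo, 5))
                return f"resid {lo} to {hi}", lambda row: lo <= row["resid"] <= hi
            if kind == "chainid":
                c = int(rng.integers(0, 2))
                return f"chainid {c}", lambda row: row["chain"] == c
            if kind == "element":
                v = str(rng.choice(["C", "N", "Na", "Cl", "O"]))
                return f"element {v}", lambda row: row["element"].upper() == v.upper()
            col = kind
            v = str(rng.choice(topo[col].unique()))
            return f"{kind} {v}", lambda row: row[col] == v

        def tree(depth):
            if depth == 0 or rng.random() < 0.4:
                return leaf()
            op = rng.choice(["and", "or", "not"])
            if op == "not":
                e, f = tree(depth - 1)
                return f"not ({e})", lambda row, f=f: not f(row)
            l_e, l_f = tree(depth - 1)
            r_e, r_f = tree(depth - 1)
            if op == "and":
                return f"({l_e}) and ({r_e})", lambda row: l_f(row) and r_f(row)
            return f"({l_e}) or ({r_e})", lambda row: l_f(row) or r_f(row)

        expr, pred = tree(3)
        brute = sorted(i for i in range(n) if pred(topo.iloc[i]))
        if not brute:
            with pytest.raises(EmptySelectionError):
                resolve_selection(topo, expr)
        else:
            assert list(resolve_selection(topo, expr)) == brute


class TestIndexFiles:
    def test_read_whitespace_and_commas(self, tmp_path):
        p = tmp_path / "idx.txt"
        p.write_text("0, 2 5\n7,7\n")
        assert list(read_index_file(p)) == [0, 2, 5, 7]

    def test_bad_token_is_format_error(self, tmp_path):
        p = tmp_path / "idx.txt"
        p.write_text("0 two 5")
        with pytest.raises(FormatError):
            read_index_file(p)
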