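"""GFA parsing, path depth, node classification, subgraph extraction."""

import io
import random

import pytest

from panloc.graph import (
    GfaError,
    classify_nodes,
    extract_subgraph,
    graph_stats,
    parse_gfa,
    path_node_depth,
    path_sequence,
    write_gfa,
)

LINEAR = """H\tVN:Z:1.0
S\t1\tACGT
S\t2\tGG
S\t3\tTTTT
L\t1\t+\t2\t+\t0M
L\t2\t+\t3\t+\t0M
P\tA#1\t1+,2+,3+\t*
"""


def test_parse_linear_graph():
    g = parse_gfa(io.StringIO(LINEAR))
    assert graph_stats(g) == (3, 2, 10, 1)
    assert g.paths["A#1"] == [("1", False), ("2", False), ("3", False)]
    assert path_sequence(g, "A#1") == "ACGTGGTTTT"


def test_w_line_equivalent_to_p_line():
    p_text = LINEAR.replace("P\tA#1\t1+,2+,3+\t*", "P\tA#1#0\t1+,2+,3+\t*")
    w_text = LINEAR.replace("P\tA#1\t1+,2+,3+\t*", "W\tA\t1\t0\t0\t10\t>1>2>3")
    gp, gw = parse_gfa(io.StringIO(p_text)), parse_gfa(io.StringIO(w_text))
    assert gw.paths == {"A#1#0": [("1", False), ("2", False), ("3", False)]}
    assert gw.paths == gp.paths
    assert gw.edges == gp.edges and gw.nodes.keys() == gp.nodes.keys()


def test_dangling_link_is_an_error():
    with pytest.raises(GfaError, match="99"):
        parse_gfa(io.StringIO(LINEAR + "L\t3\t+\t99\t+\t0M\n"))


def test_path_referencing_missing_node_names_path_and_node():
    with pytest.raises(GfaError, match=r"B#1.*77"):
        parse_gfa(io.StringIO(LINEAR + "P\tB#1\t1+,77+\t*\n"))


def test_sequenceless_node_requires_ln_tag():
    g = parse_gfa(io.StringIO("S\tx\t*\tLN:i:12\n"))
    assert g.node_length("x") == 12
    with pytest.raises(GfaError, match="LN"):
        parse_gfa(io.StringIO("S\tx\t*\n"))


def test_write_parse_round_trip(small_cohort):
    buf = io.StringIO()
    write_gfa(small_cohort.graph, buf)
    back = parse_gfa(io.StringIO(buf.getvalue()))
    assert graph_stats(back) == graph_stats(small_cohort.graph)
    assert back.paths == small_cohort.graph.paths


def test_every_path_spells_its_haplotype(small_cohort):
    for hap in small_cohort.haplotypes:
        assert path_sequence(small_cohort.graph, hap.name) == hap.sequence


# ---------------------------------------------------------------------------
# depth


def test_depth_counts_distinct_samples_not_paths():
    text = LINEAR + "P\tA#2\t1+,3+\t*\nP\tB#1\t1+,2+,3+\t*\n"
    table = path_node_depth(parse_gfa(io.StringIO(text)))
    assert table.n_samples == 2
    assert table.depth == {"1": 2, "2": 2, "3": 2}
    assert table.samples["2"] == frozenset({"A", "B"})


def test_cycle_multiplicity_counts_every_traversal():
    text = (
        "S\ta\tAA\nS\tu\tCC\nS\tb\tGG\n"
        "P\tC#1\ta+,u+,u+,u+,b+\t*\nP\tN#1\ta+,b+\t*\n"
    )
    table = path_node_depth(parse_gfa(io.StringIO(text)))
    assert table.multiplicity["u"] == {"C#1": 3}
    assert table.depth["u"] == 1  # one sample, however many traversals


def test_depth_matches_brute_force_on_random_graphs():
    rng = random.Random(11)
    for _ in range(20):
        nodes = [f"n{i}" for i in range(rng.randint(2, 12))]
        lines = [f"S\t{n}\t{'A' * rng.randint(1, 5)}" for n in nodes]
        paths = {}
        for s in range(rng.randint(1, 5)):
            for h in range(rng.randint(1, 2)):
                name = f"S{s}#{h}"
                steps = [rng.choice(nodes) for _ in range(rng.randint(1, 15))]
                paths[name] = steps
                lines.append(f"P\t{name}\t{','.join(x + '+' for x in steps)}\t*")
        g = parse_gfa(io.StringIO("\n".join(lines) + "\n"))
        table = path_node_depth(g)
        for n in nodes:
            samples = {p.split("#")[0] for p, steps in paths.items() if n in steps}
            assert table.depth[n] == len(samples)
            for p, steps in paths.items():
                assert table.multiplicity.get(n, {}).get(p, 0) == steps.count(n)


def test_depth_conservation_along_paths(small_cohort):
    """Sum of multiplicity x node length per path equals the path's sequence length."""
    g = small_cohort.graph
    table = path_node_depth(g)
    for name in g.paths:
        total = sum(
            mult * g.node_length(n)
            for n, per_path in table.multiplicity.items()
            for p, mult in per_path.items()
            if p == name
        )
        assert total == len(path_sequence(g, name))


# ---------------------------------------------------------------------------
# classification


def test_classification_by_depth():
    text = LINEAR + "P\tB#1\t1+,2+\t*\nP\tC#1\t1+\t*\n"
    g = parse_gfa(io.StringIO(text))
    classes = classify_nodes(path_node_depth(g))
    assert classes["1"] == "core"  # all 3 samples
    assert classes["2"] == "variable"  # 2 of 3
    assert classes["3"] == "private"  # A only
    assert classes.counts == {"core": 1, "variable": 1, "private": 1}


def test_classification_partitions_traversed_nodes(small_cohort):
    table = path_node_depth(small_cohort.graph)
    classes = classify_nodes(table)
    traversed = {n for n, d in table.depth.items() if d > 0}
    assert set(classes.labels) == traversed
    assert sum(classes.counts.values()) == len(traversed)


def test_depth_exceeding_n_samples_is_an_error():
    two_samples = LINEAR + "P\tB#1\t1+,2+,3+\t*\n"
    table = path_node_depth(parse_gfa(io.StringIO(two_samples)))
    with pytest.raises(ValueError, match="inconsistent"):
        classify_nodes(table, n_samples=1)
    with pytest.raises(ValueError):
        classify_nodes(table, n_samples=0)


# ---------------------------------------------------------------------------
# extraction and stats


def test_stats_total_bp_and_relabel_invariance():
    g = parse_gfa(io.StringIO("S\tx\t" + "A" * 10 + "\nS\ty\t" + "C" * 20 + "\nS\tz\t" + "G" * 30 + "\n"))
    assert graph_stats(g).total_bp == 60
    relabeled = parse_gfa(
        io.StringIO("S\tq\t" + "A" * 10 + "\nS\tr\t" + "C" * 20 + "\nS\ts\t" + "G" * 30 + "\n")
    )
    assert graph_stats(relabeled) == graph_stats(g)


def test_extract_full_node_set_is_identity(small_cohort):
    g = small_cohort.graph
    sub = extract_subgraph(g, g.nodes.keys(), flank=0)
    assert graph_stats(sub) == graph_stats(g)
    assert sub.paths == g.paths


def test_extract_is_idempotent(small_cohort):
    g = small_cohort.graph
    sv = list(small_cohort.truth.sv_nodes)
    once = extract_subgraph(g, sv, flank=10)
    twice = extract_subgraph(once, sv, flank=10)
    assert twice.nodes.keys() == once.nodes.keys()
    assert twice.edges == once.edges
    assert twice.paths == once.paths


def test_extract_sv_nodes_keeps_carrier_traversals(small_cohort):
    g = small_cohort.graph
    sub = extract_subgraph(g, small_cohort.truth.sv_nodes, flank=3)
    carriers = {h.name for h in small_cohort.haplotypes if h.carrier}
    sv = small_cohort.truth.sv_nodes[0]
    for name, steps in sub.paths.items():
        base = name.split("_part")[0]
        if base in carriers:
            continue
        assert all(n != sv for n, _ in steps)
    kept_carriers = {n.split("_part")[0] for n in sub.paths} & carriers
    assert kept_carriers == carriers


def test_disjoint_node_set_splits_paths_into_parts():
    g = parse_gfa(io.StringIO(LINEAR))
    sub = extract_subgraph(g, ["1", "3"], flank=0)
    assert set(sub.paths) == {"A#1_part1", "A#1_part2"}
    assert sub.paths["A#1_part1"] == [("1", False)]


def test_extract_empty_set_is_an_error(small_cohort):
    with pytest.raises(ValueError):
        extract_subgraph(small_cohort.graph, [])
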