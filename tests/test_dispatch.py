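"""Tool dispatch: configs, conversion, parsing, custom tools, stubs."""

import json
import os
import shutil

import pytest

import molevo as m
from molevo.dispatch import ToolProfile, run_aligner, run_inference

ECHO_ALIGNER = """\
import sys
sys.stdout.write(open(sys.argv[-1]).read())
"""

RECORDING_ALIGNER = """\
import json, sys
with open({record_file!r}, "w") as fh:
    json.dump({{"argv": sys.argv[1:], "input": open(sys.argv[-1]).read()}}, fh)
sys.stdout.write(open(sys.argv[-1]).read())
"""

TREE_TOOL = """\
import sys
print("(A,B,(C,D));")
print("Log-Likelihood: -1234.5", file=sys.stderr)
"""


def _profile(executable, task="alignment", **kw):
    kw.setdefault("input_formats", ("fasta",))
    kw.setdefault("configs", {"default": ()})
    return ToolProfile(name="stub", executable=executable, task=task, **kw)


class TestConfigs:
    def test_no_arguments_resolves_to_default(self):
        assert m.get_config("fasttree") == ["-gtr", "-nt"]

    def test_mafft_default_is_auto(self):
        assert "--auto" in m.get_config("mafft", "default")

    def test_explicit_list_passes_through(self):
        args = ["--op", "5", "--custom"]
        assert m.get_config("mafft", args) == args

    def test_unknown_keyword_lists_alternatives(self):
        with pytest.raises(m.UnknownKeywordError, match="default"):
            m.get_config("mafft", "no-such-keyword")

    def test_inference_keywords_follow_model_plus_method_scheme(self):
        profile = m.get_profile("fasttree")
        assert "gtr+cat" in profile.configs and "gtr+gamma" in profile.configs

    def test_every_builtin_profile_has_default(self):
        from molevo.dispatch import registered_tools

        for name in registered_tools():
            assert "default" in m.get_profile(name).configs


class TestAligner:
    def test_genbank_input_converted_to_fasta_for_the_tool(
        self, write_stub, tmp_path
    ):
        record_file = str(tmp_path / "seen.json")
        stub = write_stub(
            "recorder", RECORDING_ALIGNER.format(record_file=record_file)
        )
        records, _ = m.make_hmtdna_panel(m.PanelSpec(n_records=2, seed=1))
        gb = str(tmp_path / "in.gb")
        m.write_genbank(records, gb)
        alignment = run_aligner(_profile(stub), gb, "genbank")
        seen = json.load(open(record_file))
        assert seen["input"].startswith(">")  # the stub received FASTA
        assert seen["argv"][-1] != gb  # via a converted temp file
        assert len(alignment) == 2
        assert str(alignment[0].seq) == records[0].sequence

    def test_identity_tool_roundtrips_sequences(self, write_stub, tmp_path):
        stub = write_stub("echoal", ECHO_ALIGNER)
        records, _ = m.make_hmtdna_panel(m.PanelSpec(n_records=3, seed=2))
        fa = str(tmp_path / "in.fa")
        m.write_fasta(records, fa)
        alignment = run_aligner(_profile(stub), fa, "fasta")
        assert [r.id for r in alignment] == [r.id for r in records]

    def test_custom_unregistered_tool_runs_with_formats_and_flag(
        self, write_stub, tmp_path
    ):
        stub = write_stub("myaligner", ECHO_ALIGNER)
        fa = str(tmp_path / "in.fa")
        m.write_fasta([m.AnnotatedRecord(id="a", sequence="ACGT")], fa)
        alignment = run_aligner(
            stub, fa, "fasta", config=[], input_formats=["fasta"], input_flag="-in"
        )
        assert len(alignment) == 1

    def test_output_file_written_in_requested_format(self, write_stub, tmp_path):
        stub = write_stub("echoal", ECHO_ALIGNER)
        fa, out = str(tmp_path / "in.fa"), str(tmp_path / "out.phy")
        m.write_fasta(
            [
                m.AnnotatedRecord(id="a", sequence="ACGT"),
                m.AnnotatedRecord(id="b", sequence="AGGT"),
            ],
            fa,
        )
        run_aligner(_profile(stub), fa, "fasta", output_path=out, output_format="phylip")
        assert open(out).read().split()[0] == "2"

    def test_missing_executable_is_descriptive_unavailable_error(self, tmp_path):
        fa = str(tmp_path / "in.fa")
        m.write_fasta([m.AnnotatedRecord(id="a", sequence="ACGT")], fa)
        with pytest.raises(m.ToolUnavailableError, match="not found"):
            run_aligner(_profile("/no/such/tool-xyz"), fa, "fasta")

    def test_failing_tool_carries_its_diagnostic(self, write_stub, tmp_path):
        stub = write_stub(
            "failing", "import sys\nprint('boom', file=sys.stderr)\nsys.exit(3)\n"
        )
        fa = str(tmp_path / "in.fa")
        m.write_fasta([m.AnnotatedRecord(id="a", sequence="ACGT")], fa)
        with pytest.raises(m.ToolExecutionError, match="boom"):
            run_aligner(_profile(stub), fa, "fasta")

    def test_failure_leaves_no_partial_output(self, write_stub, tmp_path):
        stub = write_stub("failing", "import sys\nsys.exit(1)\n")
        fa, out = str(tmp_path / "in.fa"), str(tmp_path / "out.fa")
        m.write_fasta([m.AnnotatedRecord(id="a", sequence="ACGT")], fa)
        with pytest.raises(m.ToolExecutionError):
            run_aligner(_profile(stub), fa, "fasta", output_path=out)
        assert not os.path.exists(out)


class TestInference:
    def test_stub_tree_and_score_parsed(self, write_stub, tmp_path):
        stub = write_stub("treestub", TREE_TOOL)
        fa = str(tmp_path / "in.fa")
        m.write_fasta([m.AnnotatedRecord(id="a", sequence="ACGT")], fa)
        profile = _profile(
            stub, task="tree", score_pattern=r"Log-Likelihood:\s*(-?\d+\.?\d*)"
        )
        tree, score = run_inference(profile, fa, "fasta")
        assert score == -1234.5
        assert m.leaf_labels(tree) == frozenset("ABCD")

    def test_bootstraps_rejected_for_incapable_profile(self, write_stub, tmp_path):
        stub = write_stub("treestub", TREE_TOOL)
        fa = str(tmp_path / "in.fa")
        m.write_fasta([m.AnnotatedRecord(id="a", sequence="ACGT")], fa)
        profile = _profile(stub, task="tree", score_pattern=r"(-?\d+\.?\d*)")
        with pytest.raises(m.CapabilityError, match="bootstrap"):
            run_inference(profile, fa, "fasta", bootstraps=100)

    def test_output_newick_matches_returned_tree(self, write_stub, tmp_path):
        stub = write_stub("treestub", TREE_TOOL)
        fa, out = str(tmp_path / "in.fa"), str(tmp_path / "out.nwk")
        m.write_fasta([m.AnnotatedRecord(id="a", sequence="ACGT")], fa)
        profile = _profile(
            stub, task="tree", score_pattern=r"Log-Likelihood:\s*(-?\d+\.?\d*)"
        )
        tree, _ = run_inference(profile, fa, "fasta", output_path=out)
        (written,) = m.read_trees(out)
        assert m.leaf_labels(written) == m.leaf_labels(tree)

    def test_unparseable_score_names_the_pattern(self, write_stub, tmp_path):
        stub = write_stub("treestub", "print('(A,B,(C,D));')\n")
        fa = str(tmp_path / "in.fa")
        m.write_fasta([m.AnnotatedRecord(id="a", sequence="ACGT")], fa)
        profile = _profile(stub, task="tree", score_pattern=r"NoSuch:(\d+)")
        with pytest.raises(m.ToolOutputError, match="NoSuch"):
            run_inference(profile, fa, "fasta")


class TestRealBinaries:
    """Integration against real tools; skipped (not failed) when absent."""

    def _require(self, tool):
        if not m.tool_available(tool):
            pytest.skip(f"{tool} executable not installed")

    def test_mafft_default_alignment(self, tmp_path):
        self._require("mafft")
        fa = str(tmp_path / "s.fa")
        m.write_fasta(
            [
                m.AnnotatedRecord(id=f"s{i}", sequence=s)
                for i, s in enumerate(
                    ["ACGTACGTAC", "ACGTACGAAC", "ACCTACGTTC", "AGGTACGTAC"]
                )
            ],
            fa,
        )
        alignment = run_aligner("mafft", fa, "fasta")
        assert len(alignment) == 4
        assert alignment.get_alignment_length() >= 10

    def test_fasttree_default_returns_tree_and_loglk(self, tmp_path):
        self._require("fasttree")
        fa = str(tmp_path / "s.fa")
        m.write_fasta(
            [
                m.AnnotatedRecord(id=f"s{i}", sequence=s)
                for i, s in enumerate(
                    ["ACGTACGTAC", "ACGTACGAAC", "ACCTACGTTC", "AGGTACGTAC"]
                )
            ],
            fa,
        )
        tree, score = run_inference("fasttree", fa, "fasta")
        assert len(m.leaf_labels(tree)) == 4
        assert score < 0
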