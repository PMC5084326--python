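{
  "mafft": {
    "executable": "mafft",
    "task": "alignment",
    "input_formats": ["fasta"],
    "input_flag": null,
    "configs": {
      "default": ["--auto"],
      "linsi": ["--localpair", "--maxiterate", "1000"],
      "ginsi": ["--globalpair", "--maxiterate", "1000"],
      "fftns": ["--retree", "2"]
    }
  },
  "clustalo": {
    "executable": "clustalo",
    "task": "alignment",
    "input_formats": ["fasta"],
    "input_flag": "-i",
    "configs": {
      "default": ["--outfmt=fa"],
      "full": ["--outfmt=fa", "--full"]
    }
  },
  "muscle": {
    "executable": "muscle",
    "task": "alignment",
    "input_formats": ["fasta"],
    "input_flag": "-in",
    "configs": {
      "default": [],
      "fast": ["-maxiters", "2"]
    }
  },
  "fasttree": {
    "executable": "fasttree",
    "task": "tree",
    "input_formats": ["fasta", "phylip"],
    "input_flag": null,
    "score_pattern": "LogLk\\s*=\\s*(-?\\d+(?:\\.\\d+)?)",
    "supports_bootstrap": false,
    "configs": {
      "default": ["-gtr", "-nt"],
      "gtr+cat": ["-gtr", "-nt"],
      "gtr+gamma": ["-gtr", "-nt", "-gamma"],
      "jc+cat": ["-nt"]
    }
  },
  "raxml": {
    "executable": "raxmlHPC",
    "task": "tree",
    "input_formats": ["phylip", "fasta"],
    "input_flag": "-s",
    "score_pattern": "Final GAMMA-based Score of best tree (-?\\d+(?:\\.\\d+)?)",
    "supports_bootstrap": true,
    "bootstrap_flag": "-N",
    "configs": {
      "default": ["-m", "GTRCAT", "-p", "12345"],
      "gtr+cat": ["-m", "GTRCAT", "-p", "12345"],
      "gtr+gamma": ["-m", "GTRGAMMA", "-p", "12345"]
    }
  }
}
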