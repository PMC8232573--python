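{
  "del(5q)": {"chroms": ["chr5"], "direction": "loss", "scope": "arm", "start": 48800000, "end": 181538259},
  "Monosomy 5": {"chroms": ["chr5"], "direction": "loss", "scope": "whole_chromosome"},
  "del(7q)": {"chroms": ["chr7"], "direction": "loss", "scope": "arm", "start": 60100000, "end": 159345973},
  "Monosomy 7": {"chroms": ["chr7"], "direction": "loss", "scope": "whole_chromosome"},
  "Trisomy 8": {"chroms": ["chr8"], "direction": "gain", "scope": "whole_chromosome"},
  "del(12p)": {"chroms": ["chr12"], "direction": "loss", "scope": "arm", "start": 0, "end": 34800000},
  "del(17p)": {"chroms": ["chr17"], "direction": "loss", "scope": "arm", "start": 0, "end": 25100000},
  "Trisomy 19": {"chroms": ["chr19"], "direction": "gain", "scope": "whole_chromosome"},
  "del(20q)": {"chroms": ["chr20"], "direction": "loss", "scope": "arm", "start": 28100000, "end": 64444167},
  "inv(16)": {"chroms": ["chr16"], "direction": null, "scope": "rearrangement"},
  "t(15;17)": {"chroms": ["chr15", "chr17"], "direction": null, "scope": "rearrangement"},
  "t(8;21)": {"chroms": ["chr8", "chr21"], "direction": null, "scope": "rearrangement"},
  "t(9;22)": {"chroms": ["chr9", "chr22"], "direction": null, "scope": "rearrangement"},
  "t(10;11)": {"chroms": ["chr10", "chr11"], "direction": null, "scope": "rearrangement"}
}
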