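chrom	length	cen_start	cen_end	excluded_arms
chr1	200000000	95000001	105000000
chr2	180000000	85000001	95000000
chr3	160000000	75000001	85000000
chr4	140000000	65000001	75000000
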