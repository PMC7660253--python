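strain	ploidy	chrI	chrII	chrIII	chrIV	chrV	chrVI	chrVII	chrVIII	chrIX	chrX	chrXI	chrXII	chrXIII	chrXIV	chrXV	chrXVI
SYN000	2	2	2	2	2	2	2	2	2	2	2	2	2	1	2	2	2
SYN001	3	3	3	3	3	3	3	2	3	3	2	3	3	3	3	3	3
SYN002	2	2	2	3	2	2	2	2	2	2	2	2	2	2	2	2	2
SYN003	1	1	1	1	1	1	1	1	1	1	1	1	1	2	1	0	1
SYN004	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	1
SYN005	2	2	2	2	2	1	2	1	2	2	2	2	2	2	2	2	2
SYN006	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
SYN007	3	3	3	2	3	3	3	3	3	3	3	2	3	3	3	3	3
SYN008	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0
SYN009	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1
SYN010	1	1	1	1	0	1	1	1	1	1	1	1	1	0	1	1	1
SYN011	2	2	2	2	2	2	2	2	2	2	2	2	2	1	2	1	2
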