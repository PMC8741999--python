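{
 "lars2_domains.tsv": "284f794cce793b3d1e56be51d054c75b8ac7bfe2dcfd80d6437c57e2a6465fd5",
 "panel183.txt": "334006860b549215154a17afafbb90e4b537bb550decc3d80a72cdc09088c392",
 "table2.tsv": "af5fce5e8701f63c706086829a69a098e59771d71b78a551c1c829e2239c7579",
 "table3.tsv": "d360a730d8bf595e43e642473ce3a94b521a9d02cf910e973d4a08c79d0346e3"
}
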