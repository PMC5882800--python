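name,symbol,source
escape_x,ARSD,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
escape_x,DDX3X,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
escape_x,EIF1AX,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
escape_x,EIF2S3,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
escape_x,GEMIN8,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
escape_x,HDHD1,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
escape_x,KAL1,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
escape_x,KDM6A,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
escape_x,OFD1,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
escape_x,PRKX,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
escape_x,RPS4X,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
escape_x,TRAPPC2,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
escape_x,TXLNG,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
escape_x,USP9X,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
escape_x,ZFX,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
escape_x,ZRSR2,X-linked escape genes with confirmed escape status and female-biased lung expression (4 cohorts)
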