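name,symbol,source
immune_x,DDX3X,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
immune_x,PRKX,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
immune_x,TXLNG,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
immune_x,L1CAM,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
immune_x,VEGFD,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
immune_x,TIMP1,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
immune_x,TLR7,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
immune_x,BTK,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
immune_x,BMP15,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
immune_x,DDX53,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
immune_x,AKAP4,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
immune_x,SRPX2,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
immune_x,GRPR,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
immune_x,CD40LG,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
immune_x,CTAG2,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
immune_x,CXORF36,X-linked immune genes with escape or heterogeneous Xi status (PANTHER/IRIS-derived immune annotation)
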