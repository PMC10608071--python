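gene_name	motif1	motif2	domains
LdSTS1	DELSD	NDLYSYNME	PF19086
LdSTS2	DEYTD	QDLYSYNNE	PF19086
LdSTS3	DEVSD	NDVYSYNME	PF19086
LdSTS6	DNVSD	NDIFSYNVE	PF19086; PF03936; PF06330
LdSTS7	DEYTD	NDLYSYNIE	PF19086
LdSTS8	DEFSD	NDIASYNVE	PF19086
LdSTS10	DEFSE	NDIASYNVE	PF19086
LdSTS11	DEYTD	NDLYSYNIE	PF19086
LdSTS12	DEYTD	NDLYSYNVE	PF19086
LdSTS14	DEFTD	NDMYSYNIE	PF19086
Cop1	DNLSD	NDIFSFNVE	PF19086
Cop2	DDWLD	NDIFSFNRE	PF19086
Cop3	DNISD	NDIFSYNVE	PF19086; PF03936; PF06330; PF19035
Cop4	DEISD	NDVYSYDME	PF19086; PF03936
Cop5	DYFFD	NDAYSWNVE	PF19086; PF03936
Cop6	DDAFQ	NDLLSFYKE	PF06330
Omp1	DNLTD	NDIYSFNIE	PF19086
Omp2	DNLSD	NDIFSYNVE	PF19086
Omp3	DEVSD	NDIFSYNVE	PF19086
Omp4	DEVSD	NDVYSYNKE	PF19086
Omp5a	DELSD	NDVYSYNVE	PF19086
Omp5b	DEVSD	NDVYSYNVE	PF19086
Omp6	DEYSD	NDLCSYNVE	PF19086
Omp7	DEYSD	NDTASYNYE	PF19086
Omp8	DDVFE	NDIMSFYKE	PF06330
Omp9	DDVFE	NDVLSFYKE	PF06330
Omp10	DDIFP	NDVLSFYKE	PF06330
ShSTS1	DDSLE	NDLMSFYKE	PF06330
ShSTS11	DEISD	NDVYSYNVE	PF19086
ShSTS18	DEYSD	QDICSYNVE	PF19086
ShSTS15	DEHSD	NDIVSYNIE	PF19086
ShSTS16	DEYSD	NDIVSYNLE	PF19086
ShSTS3	DDWVD	NEASSYVKE	PF19086
ShSTS4	DDYID	NDFFSYLKE	PF19086
ShSTS5	DDLSD	NDLCSFNKE	PF19086
ShSTS7	DDWTD	NDIFSYNVE	PF19086
ShSTS8	DEISD	NDIYSYDME	PF19086
ShSTS10	DEISD	NDVYSYKVE	PF19086
ShSTS12	DEISD	QDVYSYSME	PF19086
ShSTS13	DDILD	NDTFSYRRE	PF19086
ShSTS17	DEHSD	SDIVSWNLE	PF19086
HS-HMGS	DDYID	NDFFSYLKE	PF19086; PF01154
CpSTS1	DEYTD	NDMCSYKKE	PF19086
CpSTS2	DELSD	NDVYSYDME	PF19086
CpSTS3	DNISD	NDIFSYNVE	PF19086
CpSTS4	DEYTD	NDLCSFRNE	PF19086
CpSTS5	DNLSD	NDIFSYNVE	PF19086
CpSTS6	DEYSD	NDLYSYNVE	PF19086
CpSTS7	DEITE	NDVFSFKVE	PF19086
CpSTS8	DEYTD	NDVYSYNME	PF19086
CpSTS9	DEYTD	NDLFSYNME	PF19086
CpSTS11	DEATD	NDIHSYNME	PF19086
CpSTS12	DEYTD	NDLYSYNME	PF19086
CpSTS13	DETTD	NDIQSYNME	PF19086
CpSTS14	DDYIL	NDIYSYKVE	PF19086
CpSTS15	DDLME	NDLFSYRKE	PF19086
CpSTS16	DESSD	NDIHSYNME	PF19086
CpSTS17	DDIIE	NDLFSYRVE	PF19086
CpSTS18	DDLSD	NDLCSFNKE	PF19086; PF03936; PF06330
AcTPS4	DEVSD	NDVYSYNME	PF19086
AcTPS5	DDWTD	NDVLSYNAE	PF19086; PF03936
AcTPS9	DEISD	NDLYSYNME	PF19086
Tps1A	DIEGD	QDFPDIEFD	PF01040
Tps2A	DVAGD	QDFPDIEFD	PF01040
AncA	DDRIE	DDFTDD	PF13419
AncC	DDKIE	DDFTDD	PF13419
BvCS	DNISD	NDVFSYNVE	PF19086; PF03936
GME3634	DDWTD	NDVLSYNAE	PF19086
GME3638	DDWSD	NDLFSYNVE	na
GME9210	DEYSD	NDIVSYNVE	PF19086
Agr1	DNLSD	NDIFSYSVE	PF19086; PF03936
Agr2	DEVTD	NDLYSYNME	PF19086
Agr3	DNISD	NDIFSYNVE	PF19086; PF03936
Agr4	DEVSD	NDVYSYDME	PF19086
Agr5	DEYTD	NDLVSYNME	PF19086
Agr6	DEHTD	NDLCSYNVE	PF19086
Agr7	DEWSD	NDLCSYNVE	PF19086
Agr8	DEYTD	NDMHSYVRE	PF19086; PF03936
Agr9	DEYTD	NDIDSYAME	PF19086
Agr10	DECAD	na	na
Agr11	DEYTD	na	PF19086
Copu1	DELTD	NDVYSYNME	PF19086
Copu2	DDLTD	NDVFSYNRE	PF19086
Copu3	DELSD	NDVYSYNME	PF19086
Copu5	DDWSD	NDVFSYNKE	PF19086; PF03936
Copu9	DDWLD	NDIFSYNKE	PF19086
Pilcr_825684	DELTD	NDLFSYNRE	PF19086
Galma_104215	DEFTD	NDLFSYDME	PF19086
Sphst_47084	DEYTD	NDLFSYNS	PF19086
Denbi1_816208	DEFTD	NDLFSYNME	PF19086
Denbi1_659367	DEHSD	NDLCSYNVE	PF19086
Hetan2_454193	DEYSD	NDIASYNLE	PF19086
Hypsu1_138665	DEHTD	NDLCSYKVE	PF19086; PF03936
Pro1	DEYSD	NDVVSYNLE	PF19086; PF03936
Hfas94a	DEYTD	NDMHSYGLE	PF19086
Hfas94b	DEDLD	NDLISYTKE	PF19086
Hfas344	DEYTD	NDMHSYALE	PF19086
Cun3817	DDLSD	NDLCSFNKE	PF19086; PF03936
Cun5155	DEHSD	NDLFSYNVE	PF19086
Cun3157	DEISD	NDIYSYNME	PF19086
Cun3158	DEVSD	NDVYSYNME	PF19086
Cun0773	DDWSD	NDILSYSKE	PF19086
Cun7050	DNISD	NDIFSYNVE	PF19086; PF03936
Cun0716	DDWSD	NDIFSFNVE	PF19086
Cun0759	DDWSD	NDIFSYNKE	PF19086
Cun3574	DDWTD	NDIFSYNKE	PF19086
Cun9106	NDDYE	na	PF06148
PpSTS01	DNISD	NDIFSYNVE	PF19086
PpSTS03	DDWSD	NDILSYNRE	PF19086; PF03936
PpSTS06	DDITD	NDIYSFNNE	PF19086
PpSTS08	DEYTD	NDLVSYNRE	PF19086
PpSTS09	DEYSD	NDMLSWNVE	PF19086
PpSTS10	DEVSD	NDVYSYNME	PF19086
PpSTS14	DEYTD	NDIASYNKE	PF19086
PpSTS29	DEPDI	NDILSFYKE	PF06330
Fompi1	DDPDI	NDILSFYKE	PF06330
PcSTS01	DNISD	NDIFSYNVE	PF19086; PF03936
PcSTS02	DEVSD	NDVYSYKME	PF19086
PcSTS03	DEISD	NDVYSYDME	PF19086
PcSTS04	DEISD	NDVYSYDME	PF19086
PcSTS06	DDFEI	NDLLSFYKE	PF06330
PcSTS08	DDEAI	NDILSFYKE	PF06330
PcSTS11	DDCEI	NDIYSFHKE	PF06330
A8411	DDYID	NDLFSYAKE	PF19086
GsSTS43	DDLSD	NDLCSFNKE	PF19086; PF03936
GsSTS45a	DDLSD	NDLCSFNKE	PF19086
GsSTS45b	DDLSD	NDLCSFNKE	PF19086
GsSTS26	DEYTD	NDVASYNRE	PF19086
GsSTS27	DEYTD	NDVASYNRE	PF19086
GS02363	DDWTD	NDVLSYNAE	PF19086; PF03936
GS14272	DNISD	NDIFSYNVE	PF19086
GS11330	DDLGE	NDILSFYKE	PF06330
GL26009	DDWTD	NDVLSYNAE	PF19086; PF03936
GLSTS6	DDLSD	NDLCSFNKE	PF19086; PF03936
STC4	DRLTD	NDLYSYKKE	PF19086
STC9	DDLSD	NDLCSFNKE	PF19086; PF03936
STC15	DNLSD	NDIFSYNVE	PF19086; PF03936
AbSTS05	DEISD	NDVYSYNVE	PF19086
AbSTS07	DDNFD	NDITSFYKE	PF06330
AbSTS09	DDNYD	NDIASFYKE	PF06330
AvSTS01	DEYTD	NDLCSYNKE	PF19086; PF03936
AvSTS03	DEYSD	NDIASYNLE	PF19086; PF03936
AvSTS06	DEFTD	NDTYSYNIE	PF19086
AvSTS07	DEFTD	NDTYSYNIE	PF19086
AvSTS09	DEVSD	NDVYSYNME	PF19086
LnSTS01	DEYSD	NDLCSYNVE	PF19086
LnSTS02	DEHSD	NDLCSYNVE	PF19086
LnSTS04	DEYSD	NDVYSYNKE	PF19086; PF03936
LnSTS09	DELSD	NDVYSYDME	PF19086
LnSTS19	DDVDS	NDLLSYHKE	PF06330
LnSTS20	DDMSS	NDILSFHKE	PF06330
LnSTS25	DDTSP	NDLMSFPKE	PF19086; PF06330
LnSTS27	DDKYF	NDIMSFYKE	PF06330
PoSTS01	DNLSD	NDIFSYNVE	PF19086; PF03936
PoSTS02	DDWLD	NDLFSYNVE	PF19086; PF03936
PoSTS03	DNISD	NDIFSYNVE	PF19086; PF03936
PoSTS05	DEVSD	NDVYSYNME	PF19086
PoSTS06	DEFSD	NDVYSWNVE	PF19086
PoSTS11	EEITE	NDIYSYKKE	PF19086
PoSTS16	DDISS	NDVLSFYKE	PF06330
TvSTS01	DNICD	NDIFSYNVE	PF19086
TvSTS05	DEISD	NDLYSYNME	PF19086
TvSTS06	DEVSD	NDVYSYNME	PF19086
TvSTS07	DEQTD	NDLLSYRKE	PF19086; PF03936
TvSTS12	DDLSD	NDLCSFNKE	PF19086; PF03936
TvSTS14	DDLGG	NDILSFYKE	PF06330
TvSTS16	DDLPG	NDLLSFYKE	PF06330
IIIS	DEYTD	NDIASYNKE	PF19086
SiTPS	DDLMD	NDVYSFDNE	PF19086; PF03936
DS3	DDKLE	DLDTT	PF13419
LbSTS4a	DDITD	NDVYSYGKE	PF19086
LbSTS6	DDVFQ	NDVLSFYKE	PF06330
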